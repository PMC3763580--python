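# Three-group partitions of the 20 amino acids for 8 physicochemical
# properties — the canonical CTD divisions. The secondary-structure helix
# group (EALMQKRH) is the anchor membership; replace this file via
# PropertyGroupTable.from_yaml() to use a different division scheme.
properties:
  - name: secondary_structure
    groups:
      helix: EALMQKRH
      strand: VIYCWFT
      coil: GNPSD
  - name: solvent_accessibility
    groups:
      buried: ALFCGIVW
      exposed: RKQEND
      intermediate: MSPTHY
  - name: van_der_waals_volume
    groups:
      small: GASTPDC
      medium: NVEQIL
      large: MHKFRYW
  - name: hydrophobicity
    groups:
      polar: RKEDQN
      neutral: GASTPHY
      hydrophobic: CLVIMFW
  - name: charge
    groups:
      positive: KR
      neutral: ANCQGHILMFPSTWYV
      negative: DE
  - name: polarizability
    groups:
      low: GASDT
      medium: CPNVEQIL
      high: KMHFRYW
  - name: polarity
    groups:
      low: LIFWCMVY
      medium: PATGS
      high: HQRKNED
  - name: surface_tension
    groups:
      high: GQDNAHR
      medium: KTSEC
      low: ILMFPWYV
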