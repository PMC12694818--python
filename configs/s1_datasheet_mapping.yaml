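# Sheet/column mapping for the study's numerical workbook ("S1 Datasheet").
#
# The workbook is not shipped with this repository; download it from the
# article's supporting information and adjust the sheet names and source
# column headers below to match the actual layout before use.  Heteroplasmy
# columns on the 0-100 scale must set `percent: true` so they are divided by
# 100 exactly once at import.

pairs:
  sheet: "Fig 2A"
  percent: true
  columns:
    mother_id: "Mother ID"
    pup_id: "Pup ID"
    generation: "Generation"
    mother_h: "Mother heteroplasmy (%)"
    pup_h: "Pup heteroplasmy (%)"

oocytes:
  sheet: "Fig 3B"
  percent: true
  columns:
    mouse_id: "Mouse ID"
    mother_h: "Mother heteroplasmy (%)"
    stage_or_day: "Follicle stage"
    h: "Oocyte heteroplasmy (%)"
  constants:
    group: "edited"

tissues:
  sheet: "Fig 1D"
  percent: true
  wide: true
  id_column: "Mouse"
  value_columns:
    - "Heart"
    - "Liver"
    - "Spleen"
    - "Lung"
    - "Kidney"
    - "Brain"
    - "Muscle"
    - "Tail"
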