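# Default alkyne-iodination parameter space and constraint set.
#
# Eight parameters; two reaction routes share the grid.  A point is on the
# NIS route iff iodine_source is NIS (no chloramine oxidant, optionally an
# acid catalyst); otherwise it is on the chloramine route (an iodide salt as
# halogen source, chloramine-B in at least stoichiometric amount, no acid
# catalyst).  Temperatures are capped a safety margin below the solvent's
# nominal boiling point (CH3CN/H2O uses the azeotrope).  With these rules the
# feasible grid has 12,036 points.  Boiling points and the margin are
# editable data, not engine behaviour.
parameters:
  - name: alkyne
    kind: categorical
    options:
      - 2-ethynyltoluene
      - 4-ethynyltoluene
      - 1-chloro-2-ethynylbenzene
      - 1-chloro-4-ethynylbenzene
  - name: chloramine_eq
    kind: ordinal-numeric
    options: [0, 1, 1.5, 2]
  - name: solvent
    kind: categorical
    options:
      - MeOH
      - CH3CN
      - CH3CN/H2O
      - THF
      - DMF
      - DMSO
      - DCM
      - EtOAc
      - "1,4-dioxane"
      - MTBE
      - DCE
  - name: iodine_source
    kind: categorical
    options: [KI, NaI, TBAI, NH4I, NIS]
  - name: iodine_source_eq
    kind: ordinal-numeric
    options: [0, 1, 1.5, 2]
  - name: catalyst
    kind: categorical
    options: [PTSA, AcOH, "none"]
  - name: catalyst_eq
    kind: ordinal-numeric
    options: [0, 0.1, 1]
  - name: temperature
    kind: ordinal-numeric
    options: [25, 35, 45, 55, 65, 75, 85, 95]

constraints:
  - rule_id: solvent-boiling-point-cap
    rule_kind: max-temperature-by-solvent
    payload:
      solvent_field: solvent
      temperature_field: temperature
      safety_margin: 5.0
      boiling_points:
        MeOH: 65
        CH3CN: 82
        CH3CN/H2O: 76
        THF: 66
        DMF: 153
        DMSO: 189
        DCM: 40
        EtOAc: 77
        "1,4-dioxane": 101
        MTBE: 55
        DCE: 84
  - rule_id: nis-excludes-chloramine
    rule_kind: conditional-requirement
    payload:
      when: {iodine_source: [NIS]}
      require: {chloramine_eq: [0]}
  - rule_id: chloramine-route-stoichiometric
    rule_kind: min-equivalents-when-active
    payload:
      when: {iodine_source: [KI, NaI, TBAI, NH4I]}
      field: chloramine_eq
      min: 1
  - rule_id: iodine-source-stoichiometric
    rule_kind: min-equivalents-when-active
    payload:
      field: iodine_source_eq
      min: 1
  - rule_id: no-acid-catalyst-with-chloramine
    rule_kind: forbidden-combination
    payload:
      a: {chloramine_eq: [1, 1.5, 2]}
      b: {catalyst: [PTSA, AcOH]}
  - rule_id: no-catalyst-no-loading
    rule_kind: conditional-requirement
    payload:
      when: {catalyst: ["none"]}
      require: {catalyst_eq: [0]}
  - rule_id: active-catalyst-needs-loading
    rule_kind: conditional-requirement
    payload:
      when: {catalyst: [PTSA, AcOH]}
      require: {catalyst_eq: [0.1, 1]}
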