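# One-way sensitivity scenarios over the 6-month service total.
scenarios:
  - {label: "base case"}
  - {label: "no London weighting", london_weighting_on: false}
  - {label: "test at 300", test_price_gbp: "300.00"}
  - {label: "test at 400", test_price_gbp: "400.00"}
  - {label: "test at 600", test_price_gbp: "600.00"}
  - {label: "test at 700", test_price_gbp: "700.00"}
  - {label: "test at 1000", test_price_gbp: "1000.00"}
  - {label: "25% consultant appointments", consultant_fraction: 0.25}
  - {label: "50% consultant appointments", consultant_fraction: 0.50}
  - {label: "75% consultant appointments", consultant_fraction: 0.75}
  - {label: "25% telephone appointments", face_to_face_fraction: 0.75}
  - {label: "50% telephone appointments", face_to_face_fraction: 0.50}
  - {label: "75% telephone appointments", face_to_face_fraction: 0.25}
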