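# Default three-level EMR quality index system.
# Weights are absolute (global-scale) fractions printed to 3 decimals;
# relative weights are derived at load time as absolute / parent absolute.
name: emr-ml-quality-index
version: "1.0"
provenance: >
  Weighted three-level indicator hierarchy for scoring the suitability of
  EMR tabular datasets for machine-learning disease-risk prediction:
  4 quality dimensions, 11 sub-dimensions, 33 computable leaf indicators.
nodes:
  # ---- Operability -------------------------------------------------------
  - {id: O, name: Operability, level: 1, weight: 0.251}
  - {id: O1, name: Integrability, level: 2, parent: O, weight: 0.091}
  - {id: O1.1, name: Ratio of mapping the primary key, level: 3, parent: O1, weight: 0.032, calculator: primary_key_mapping}
  - {id: O1.2, name: Ratio of mapping data elements, level: 3, parent: O1, weight: 0.030, calculator: element_mapping}
  - {id: O1.3, name: Ratio of interconvertible data elements, level: 3, parent: O1, weight: 0.029, calculator: unit_convertibility}
  - {id: O2, name: Portability, level: 2, parent: O, weight: 0.082}
  - {id: O2.1, name: Reliable data migration, level: 3, parent: O2, weight: 0.082, calculator: reliable_migration}
  - {id: O3, name: Selectivity, level: 2, parent: O, weight: 0.078}
  - {id: O3.1, name: Sufficient data elements as inputs for feature engineering, level: 3, parent: O3, weight: 0.020, calculator: input_sufficiency}
  - {id: O3.2, name: Sufficient data elements as outputs for feature engineering, level: 3, parent: O3, weight: 0.019, calculator: output_sufficiency}
  - {id: O3.3, name: Measurement selectivity in data inputs for feature engineering, level: 3, parent: O3, weight: 0.020, calculator: input_method_selectivity}
  - {id: O3.4, name: Measurement selectivity in data outputs for feature engineering, level: 3, parent: O3, weight: 0.019, calculator: output_method_selectivity}
  # ---- Completeness ------------------------------------------------------
  - {id: C, name: Completeness, level: 1, weight: 0.254}
  - {id: C1, name: Integrity of data elements, level: 2, parent: C, weight: 0.066}
  - {id: C1.1, name: Integrity of data elements as inputs in predictive modeling, level: 3, parent: C1, weight: 0.017, calculator: input_element_integrity}
  - {id: C1.2, name: Integrity of data elements as outputs in predictive modeling, level: 3, parent: C1, weight: 0.016, calculator: output_element_integrity}
  - {id: C1.3, name: Integrity of data values as inputs in predictive modeling, level: 3, parent: C1, weight: 0.017, calculator: input_value_integrity}
  - {id: C1.4, name: Integrity of data values as outputs in predictive modeling, level: 3, parent: C1, weight: 0.016, calculator: output_value_integrity}
  - {id: C2, name: Integrity of temporal information, level: 2, parent: C, weight: 0.062}
  - {id: C2.1, name: Integrity of timestamps as creating data, level: 3, parent: C2, weight: 0.032, calculator: record_timestamp_integrity}
  - {id: C2.2, name: Integrity of timestamps as creating values with data, level: 3, parent: C2, weight: 0.031, calculator: value_timestamp_integrity}
  - {id: C3, name: Integrity of data state, level: 2, parent: C, weight: 0.063}
  - {id: C3.1, name: Integrity of data state in available, level: 3, parent: C3, weight: 0.063, calculator: state_availability}
  - {id: C4, name: Data balance, level: 2, parent: C, weight: 0.063}
  - {id: C4.1, name: Adequate data, level: 3, parent: C4, weight: 0.020, calculator: sample_adequacy}
  - {id: C4.2, name: Balance of input data, level: 3, parent: C4, weight: 0.021, calculator: input_balance}
  - {id: C4.3, name: Balance of output data, level: 3, parent: C4, weight: 0.022, calculator: output_balance}
  # ---- Correctness -------------------------------------------------------
  - {id: R, name: Correctness, level: 1, weight: 0.264}
  - {id: R1, name: Data accuracy, level: 2, parent: R, weight: 0.087}
  - {id: R1.1, name: Accurate data formats, level: 3, parent: R1, weight: 0.013, calculator: format_accuracy}
  - {id: R1.2, name: Accurate data types, level: 3, parent: R1, weight: 0.015, calculator: type_accuracy}
  - {id: R1.3, name: Right level of granularity, level: 3, parent: R1, weight: 0.015, calculator: granularity}
  - {id: R1.4, name: Accurate measurement of data, level: 3, parent: R1, weight: 0.015, calculator: range_conformance}
  - {id: R1.5, name: Unambiguity of data elements, level: 3, parent: R1, weight: 0.015, calculator: element_unambiguity}
  - {id: R1.6, name: Unambiguity of measurement of data, level: 3, parent: R1, weight: 0.014, calculator: method_unambiguity}
  - {id: R2, name: Data consistency, level: 2, parent: R, weight: 0.089}
  - {id: R2.1, name: Consistent measurement of data, level: 3, parent: R2, weight: 0.031, calculator: method_consistency}
  - {id: R2.2, name: Consistent metric calculations, level: 3, parent: R2, weight: 0.030, calculator: derived_value_consistency}
  - {id: R2.3, name: Consistent metric units, level: 3, parent: R2, weight: 0.028, calculator: unit_consistency}
  - {id: R3, name: Data compliance, level: 2, parent: R, weight: 0.089}
  - {id: R3.1, name: Data elements for compliance, level: 3, parent: R3, weight: 0.023, calculator: element_terminology_compliance}
  - {id: R3.2, name: Data measurement for compliance, level: 3, parent: R3, weight: 0.022, calculator: value_terminology_compliance}
  - {id: R3.3, name: Standard timestamps for compliance, level: 3, parent: R3, weight: 0.022, calculator: timestamp_standard_compliance}
  - {id: R3.4, name: Standard time logs for compliance, level: 3, parent: R3, weight: 0.023, calculator: temporal_order_compliance}
  # ---- Timeliness --------------------------------------------------------
  - {id: T, name: Timeliness, level: 1, weight: 0.231}
  - {id: T1, name: Data timeliness, level: 2, parent: T, weight: 0.231}
  - {id: T1.1, name: Timeliness on recording data, level: 3, parent: T1, weight: 0.113, calculator: recording_timeliness}
  - {id: T1.2, name: Frequency on recording data, level: 3, parent: T1, weight: 0.118, calculator: recording_frequency}
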