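# Editable default method assumptions. The pill (13 cycles per year of
# coverage, 1/15 CYP per cycle) and 10-year IUD (4.6 CYP) values follow the
# published USAID CYP conventions; the CCR tables and remaining CYP factors
# are illustrative defaults meant to be replaced with a programme's own
# current assumption set.
median_age_sterilisation: 33.0
methods:
  - name: iud_10yr
    category: long-acting
    max_duration: 10
    ccr_file: ccr_iud_10yr.csv
    cyp_factor: 4.6
  - name: iud_5yr
    category: long-acting
    max_duration: 5
    ccr_file: ccr_iud_5yr.csv
    cyp_factor: 3.3
  - name: implant_5yr
    category: long-acting
    max_duration: 5
    ccr_file: ccr_implant_5yr.csv
    cyp_factor: 3.8
  - name: implant_4yr
    category: long-acting
    max_duration: 4
    ccr_file: ccr_implant_4yr.csv
    cyp_factor: 3.2
  - name: implant_3yr
    category: long-acting
    max_duration: 3
    ccr_file: ccr_implant_3yr.csv
    cyp_factor: 2.5
  - name: female_sterilisation
    category: permanent
    cyp_factor: 10.0
  - name: male_sterilisation
    category: permanent
    cyp_factor: 10.0
  - name: pill
    category: short-term
    units_per_year: 13.0
    cyp_factor: 0.06666666666666667
  - name: injectable_3mo
    category: short-term
    units_per_year: 4.0
    cyp_factor: 0.25
  - name: condom
    category: short-term
    units_per_year: 120.0
    cyp_factor: 0.008333333333333333
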