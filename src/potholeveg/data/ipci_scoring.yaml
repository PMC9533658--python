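# Index of Plant Community Integrity scoring configuration, version 1.
#
# Nine plant-community metrics are each scored 0/4/7/11 from the value
# ranges below (separate ranges per hydrologic class), summed to a 0-99
# total, and the total is mapped to a condition category.  Ranges are
# stated at each metric's printed precision (counts: integer; percentage:
# 1 decimal; average C and FQI: 2 decimals); values are rounded
# half-away-from-zero to that precision before lookup, so the ranges
# partition each metric's achievable domain exactly.  A null upper bound
# means unbounded above.  Adapting the index to another region is an edit
# to this file, not a code change.
version: 1
metrics:
  richness_native_perennial: {precision: 0}
  genera_native_perennial: {precision: 0}
  native_grass_grasslike: {precision: 0}
  pct_annual_biennial_introduced: {precision: 1}
  wetmeadow_native_perennial: {precision: 0}
  count_c_ge_5: {precision: 0}
  wetmeadow_count_c_ge_4: {precision: 0}
  avg_c: {precision: 2}
  fqi: {precision: 2}
scoring:
  temporarily_ponded:
    richness_native_perennial:
      - {score: 0, lo: 0, hi: 16}
      - {score: 4, lo: 17, hi: 23}
      - {score: 7, lo: 24, hi: 40}
      - {score: 11, lo: 41, hi: null}
    genera_native_perennial:
      - {score: 0, lo: 0, hi: 11}
      - {score: 4, lo: 12, hi: 19}
      - {score: 7, lo: 20, hi: 26}
      - {score: 11, lo: 27, hi: null}
    native_grass_grasslike:
      - {score: 0, lo: 0, hi: 8}
      - {score: 4, lo: 9, hi: 10}
      - {score: 7, lo: 11, hi: 15}
      - {score: 11, lo: 16, hi: null}
    pct_annual_biennial_introduced:
      - {score: 0, lo: 41.1, hi: null}
      - {score: 4, lo: 35.1, hi: 41.0}
      - {score: 7, lo: 27.1, hi: 35.0}
      - {score: 11, lo: 0.0, hi: 27.0}
    wetmeadow_native_perennial:
      - {score: 0, lo: 0, hi: 7}
      - {score: 4, lo: 8, hi: 10}
      - {score: 7, lo: 11, hi: 13}
      - {score: 11, lo: 14, hi: null}
    count_c_ge_5:
      - {score: 0, lo: 0, hi: 4}
      - {score: 4, lo: 5, hi: 11}
      - {score: 7, lo: 12, hi: 16}
      - {score: 11, lo: 17, hi: null}
    wetmeadow_count_c_ge_4:
      - {score: 0, lo: 0, hi: 3}
      - {score: 4, lo: 4, hi: 9}
      - {score: 7, lo: 10, hi: 12}
      - {score: 11, lo: 13, hi: null}
    avg_c:
      - {score: 0, lo: 0.00, hi: 2.50}
      - {score: 4, lo: 2.51, hi: 3.57}
      - {score: 7, lo: 3.58, hi: 4.58}
      - {score: 11, lo: 4.59, hi: null}
    fqi:
      - {score: 0, lo: 0.00, hi: 13.60}
      - {score: 4, lo: 13.61, hi: 21.70}
      - {score: 7, lo: 21.71, hi: 27.20}
      - {score: 11, lo: 27.21, hi: null}
  seasonally_ponded:
    richness_native_perennial:
      - {score: 0, lo: 0, hi: 19}
      - {score: 4, lo: 20, hi: 31}
      - {score: 7, lo: 32, hi: 41}
      - {score: 11, lo: 42, hi: null}
    genera_native_perennial:
      - {score: 0, lo: 0, hi: 14}
      - {score: 4, lo: 15, hi: 24}
      - {score: 7, lo: 25, hi: 32}
      - {score: 11, lo: 33, hi: null}
    native_grass_grasslike:
      - {score: 0, lo: 0, hi: 6}
      - {score: 4, lo: 7, hi: 10}
      - {score: 7, lo: 11, hi: 17}
      - {score: 11, lo: 18, hi: null}
    pct_annual_biennial_introduced:
      - {score: 0, lo: 41.1, hi: null}
      - {score: 4, lo: 30.8, hi: 41.0}
      - {score: 7, lo: 21.1, hi: 30.7}
      - {score: 11, lo: 0.0, hi: 21.0}
    wetmeadow_native_perennial:
      - {score: 0, lo: 0, hi: 8}
      - {score: 4, lo: 9, hi: 16}
      - {score: 7, lo: 17, hi: 24}
      - {score: 11, lo: 25, hi: null}
    count_c_ge_5:
      - {score: 0, lo: 0, hi: 7}
      - {score: 4, lo: 8, hi: 17}
      - {score: 7, lo: 18, hi: 26}
      - {score: 11, lo: 27, hi: null}
    wetmeadow_count_c_ge_4:
      - {score: 0, lo: 0, hi: 4}
      - {score: 4, lo: 5, hi: 9}
      - {score: 7, lo: 10, hi: 16}
      - {score: 11, lo: 17, hi: null}
    avg_c:
      - {score: 0, lo: 0.00, hi: 2.60}
      - {score: 4, lo: 2.61, hi: 3.12}
      - {score: 7, lo: 3.13, hi: 3.52}
      - {score: 11, lo: 3.53, hi: null}
    fqi:
      - {score: 0, lo: 0.00, hi: 10.00}
      - {score: 4, lo: 10.01, hi: 16.11}
      - {score: 7, lo: 16.12, hi: 22.99}
      - {score: 11, lo: 23.00, hi: null}
categories:
  temporarily_ponded:
    - {category: Poor, lo: 0, hi: 33}
    - {category: Fair, lo: 34, hi: 66}
    - {category: Good, lo: 67, hi: 99}
  seasonally_ponded:
    - {category: "Very poor", lo: 0, hi: 19}
    - {category: Poor, lo: 20, hi: 39}
    - {category: Fair, lo: 40, hi: 59}
    - {category: Good, lo: 60, hi: 79}
    - {category: "Very good", lo: 80, hi: 99}
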