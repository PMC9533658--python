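"""Hand-encoded scoring oracle: literal threshold chains transcribed
independently of the packaged YAML configuration."""


# ---------------------------------------------------------------------------
# independent oracle: literal threshold chains for both hydrologic classes
# (values transcribed by hand from the published scoring tables)

def oracle_score(metric, value, cls):
    t = cls == "temporarily_ponded"
    if metric == "richness_native_perennial":
        cuts = (17, 24, 41) if t else (20, 32, 42)
    elif metric == "genera_native_perennial":
        cuts = (12, 20, 27) if t else (15, 25, 33)
    elif metric == "native_grass_grasslike":
        cuts = (9, 11, 16) if t else (7, 11, 18)
    elif metric == "wetmeadow_native_perennial":
        cuts = (8, 11, 14) if t else (9, 17, 25)
    elif metric == "count_c_ge_5":
        cuts = (5, 12, 17) if t else (8, 18, 27)
    elif metric == "wetmeadow_count_c_ge_4":
        cuts = (4, 10, 13) if t else (5, 10, 17)
    elif metric == "avg_c":
        cuts = (2.51, 3.58, 4.59) if t else (2.61, 3.13, 3.53)
    elif metric == "fqi":
        cuts = (13.61, 21.71, 27.21) if t else (10.01, 16.12, 23.00)
    elif metric == "pct_annual_biennial_introduced":
        # reversed orientation: high percentage is bad
        hi = 41.1
        mid = 35.1 if t else 30.8
        lo = 27.1 if t else 21.1
        if value >= hi:
            return 0
        if value >= mid:
            return 4
        if value >= lo:
            return 7
        return 11
    else:
        raise KeyError(metric)
    a, b, c = cuts
    if value < a:
        return 0
    if value < b:
        return 4
    if value < c:
        return 7
    return 11


def oracle_category(total, cls):
    if cls == "temporarily_ponded":
        return "Poor" if total <= 33 else ("Fair" if total <= 66 else "Good")
    if total <= 19:
        return "Very poor"
    if total <= 39:
        return "Poor"
    if total <= 59:
        return "Fair"
    if total <= 79:
        return "Good"
    return "Very good"


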