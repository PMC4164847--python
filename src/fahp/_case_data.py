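"""Verbatim data of the bundled forest-harvesting case study.

A sustainability comparison of two timber-extraction systems in Shaowu city
(Fujian): light cableway skidding versus road-cutting skidding, over a
three-benefit hierarchy (ecological / economic / social) with 39 leaf
indicators.  The tables here carry the published local weights, the
standardized leaf values per alternative, the per-leaf integrated values,
the two expert comparison matrices that were published in full (goal level
and the natural-ecology criterion), and the field cost measurements.

Weight entries not re-derivable from a published comparison matrix are
stored as given; the two published matrices let the weight pipeline be
re-run end to end for their nodes.
"""

from __future__ import annotations

ALTERNATIVES = ("road", "cableway")

# id -> (label, children) for internal nodes
INTERNAL = {
    "A": ("Sustainable forestry development", ("B1", "B2", "B3")),
    "B1": ("Ecological benefits", ("C11", "C12", "C13")),
    "B2": ("Economic benefits", ("C21", "C22", "C23")),
    "B3": ("Social benefits", ("C31", "C32", "C33")),
    "C11": ("Natural ecology", ("D1", "D2", "D3", "D4", "D5")),
    "C12": ("Ecological protection", ("D6", "D7", "D8", "D9")),
    "C13": ("Ecological environment", ("D10", "D11", "D12", "D13")),
    "C21": ("Cost of production", ("D14", "D15", "D16")),
    "C22": ("Production efficiency", ("D17", "D18", "D19")),
    "C23": ("Input of production", ("D20", "D21", "D22")),
    "C31": ("Forest resources", ("D23", "D24", "D25", "D26")),
    "C32": ("Technological education",
            ("D27", "D28", "D29", "D30", "D31", "D32", "D33", "D34", "D35")),
    "C33": ("Humanization index", ("D36", "D37", "D38", "D39")),
}

# id -> (label, direction)
LEAVES = {
    "D1": ("Integrity of forestry landscape", "positive"),
    "D2": ("Diversity index", "positive"),
    "D3": ("Plantation productivity", "positive"),
    "D4": ("Fertility index", "positive"),
    "D5": ("Stability index", "positive"),
    "D6": ("Water source conservation", "positive"),
    "D7": ("Soil and water conservation", "positive"),
    "D8": ("Air purifying", "positive"),
    "D9": ("Soil improving", "positive"),
    "D10": ("Biomass of forest", "positive"),
    "D11": ("Defending the remaining woods", "positive"),
    "D12": ("Afforestation effect", "positive"),
    "D13": ("Vegetation coverage", "positive"),
    "D14": ("Unit cost for ready (100 million yuan)", "reverse"),
    "D15": ("Saving rate of unit cost", "positive"),
    "D16": ("Pollution controlled cost (100 million yuan)", "reverse"),
    "D17": ("Utilization rate of forest resources", "positive"),
    "D18": ("Utilization rate of equipment", "positive"),
    "D19": ("Per capita work efficiency (m3/man)", "positive"),
    "D20": ("Increment of value of annual forest production (10,000 yuan)",
            "positive"),
    "D21": ("Annual proportion of fixed investment (%)", "positive"),
    "D22": ("Annual proportion of construction investment (%)", "positive"),
    "D23": ("Forestry area (10,000 hm2)", "positive"),
    "D24": ("Unit area amount of growing stock (m3/hm2)", "positive"),
    "D25": ("Forestry land area (10,000 hm2)", "positive"),
    "D26": ("Structural integrity of forestry", "positive"),
    "D27": ("Improvement of scientific level", "graded"),
    "D28": ("Improvement of educational level", "positive"),
    "D29": ("Policies and regulations", "positive"),
    "D30": ("Benefit future generations", "positive"),
    "D31": ("Benefit other industries", "positive"),
    "D32": ("Numbers of professionals", "positive"),
    "D33": ("Ratio of trained staff to entire staff", "positive"),
    "D34": ("Investment of science and technology project and key laboratory",
            "positive"),
    "D35": ("Number of science and technology projects", "positive"),
    "D36": ("Reducing labor intensity", "graded"),
    "D37": ("Advancement of operation and technology", "positive"),
    "D38": ("Operation technical safety", "positive"),
    "D39": ("Harmony of man-machine environment", "positive"),
}

# published local weights, by parent node (ordered as the children above)
LOCAL_WEIGHTS = {
    "A": (0.5954, 0.2763, 0.1283),
    "B1": (0.2763, 0.5954, 0.1283),
    "B2": (0.3011, 0.4536, 0.2453),
    "B3": (0.2392, 0.4422, 0.3186),
    "C11": (0.0647, 0.1665, 0.3310, 0.3310, 0.1068),
    "C12": (0.2046, 0.3403, 0.2505, 0.2046),
    "C13": (0.3309, 0.1794, 0.2201, 0.2696),
    "C21": (0.3106, 0.4361, 0.2533),
    "C22": (0.4361, 0.3106, 0.2533),
    "C23": (0.2224, 0.3357, 0.4419),
    "C31": (0.1793, 0.2201, 0.2696, 0.3310),
    "C32": (0.1376, 0.1201, 0.1049, 0.1614, 0.1260,
            0.1026, 0.0781, 0.0804, 0.0889),
    "C33": (0.1931, 0.3205, 0.2248, 0.2616),
}

# leaf -> (road standard value, cableway standard value)
STANDARD_VALUES = {
    "D1": (0.66, 0.78), "D2": (0.73, 0.76), "D3": (0.62, 0.79),
    "D4": (0.61, 0.65), "D5": (0.53, 0.82),
    "D6": (0.47, 0.58), "D7": (0.35, 0.65), "D8": (0.67, 0.71),
    "D9": (0.36, 0.76),
    "D10": (0.52, 0.57), "D11": (0.68, 0.96), "D12": (0.45, 0.95),
    "D13": (0.89, 0.98),
    "D14": (0.0, 1.0), "D15": (0.0, 0.29), "D16": (0.0, 1.0),
    "D17": (0.56, 0.78), "D18": (0.75, 0.89), "D19": (0.074, 0.112),
    "D20": (0.30, 0.35), "D21": (0.10, 0.15), "D22": (0.40, 0.40),
    "D23": (0.63, 0.69), "D24": (0.39, 0.44), "D25": (0.56, 0.66),
    "D26": (0.79, 0.87),
    "D27": (0.16, 0.86), "D28": (0.15, 0.89), "D29": (0.67, 0.78),
    "D30": (0.25, 0.53), "D31": (0.27, 0.70), "D32": (0.08, 0.13),
    "D33": (0.78, 1.00), "D34": (0.0, 0.10), "D35": (0.0, 0.10),
    "D36": (0.35, 0.89), "D37": (0.37, 0.90), "D38": (0.68, 0.76),
    "D39": (0.56, 0.86),
}

# leaf -> (road integrated value, cableway integrated value), as published
INTEGRATED_VALUES = {
    "D1": (0.0070, 0.0083), "D2": (0.0200, 0.0208), "D3": (0.0338, 0.0430),
    "D4": (0.0332, 0.0354), "D5": (0.0093, 0.0144),
    "D6": (0.0341, 0.0421), "D7": (0.0422, 0.0784), "D8": (0.0595, 0.0630),
    "D9": (0.0261, 0.0551),
    "D10": (0.0131, 0.0144), "D11": (0.0093, 0.0132),
    "D12": (0.0076, 0.0160), "D13": (0.0183, 0.0202),
    "D14": (0.0, 0.0258), "D15": (0.0, 0.0105), "D16": (0.0, 0.0211),
    "D17": (0.0306, 0.0426), "D18": (0.0292, 0.0346),
    "D19": (0.0023, 0.0036),
    "D20": (0.0045, 0.0052), "D21": (0.0023, 0.0034),
    "D22": (0.0120, 0.0120),
    "D23": (0.0035, 0.0038), "D24": (0.0026, 0.0030),
    "D25": (0.0046, 0.0055), "D26": (0.0080, 0.0088),
    "D27": (0.0012, 0.0067), "D28": (0.0010, 0.0061),
    "D29": (0.0040, 0.0046), "D30": (0.0023, 0.0049),
    "D31": (0.0019, 0.0050), "D32": (0.0005, 0.0008),
    "D33": (0.0035, 0.0044), "D34": (0.0, 0.0005), "D35": (0.0, 0.0005),
    "D36": (0.0028, 0.0070), "D37": (0.0048, 0.0118),
    "D38": (0.0062, 0.0070), "D39": (0.0060, 0.0092),
}

# published aggregated judgment matrices: node -> {(child_i, child_j): f_ij}
JUDGMENTS = {
    "A": {
        ("B1", "B2"): 1.0, ("B1", "B3"): 1.0, ("B2", "B3"): 1.0,
    },
    "C11": {
        ("D1", "D2"): 0.0, ("D1", "D3"): 0.0, ("D1", "D4"): 0.0,
        ("D1", "D5"): 0.0,
        ("D2", "D3"): 0.0, ("D2", "D4"): 0.0, ("D2", "D5"): 1.0,
        ("D3", "D4"): 0.5, ("D3", "D5"): 1.0,
        ("D4", "D5"): 1.0,
    },
}

# field cost/labor measurements per skidding system (per-m3 values in yuan
# except the quantities and efficiencies)
COST_ROWS = [
    {
        "alternative_id": "road",
        "cutting_area_code": "122-1-3",
        "working_quantity_ready": 158.00,
        "ready_cost": 16.26,
        "skidding_quantity": 1161.20,
        "skidding_cost": 119.47,
        "total_working_quantity": 1319.2,
        "fuel_cost": 7.71,
        "equipment_depreciation_cost": 5.00,
        "day_efficiency_m3_per_man": 0.74,
        "year_efficiency_m3_per_man": 185.74,
        "unit_cost": 148.44,
    },
    {
        "alternative_id": "cableway",
        "cutting_area_code": "122-1-3",
        "working_quantity_ready": 120.00,
        "ready_cost": 12.35,
        "skidding_quantity": 747.10,
        "skidding_cost": 76.86,
        "total_working_quantity": 867.1,
        "fuel_cost": 9.96,
        "equipment_depreciation_cost": 5.48,
        "day_efficiency_m3_per_man": 1.12,
        "year_efficiency_m3_per_man": 281.12,
        "unit_cost": 104.65,
    },
]
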