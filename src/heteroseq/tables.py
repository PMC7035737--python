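"""Published per-tissue summary cells from a two-hybrid neo-tetraploid rice
trio experiment (hybrids H1 x H8 and T485 x H8, eight tissue contexts).

These printed count cells are inputs to the fixture-mode summary
arithmetic: per-hybrid DEGFu-sp totals, tissue-type sums, non-additive
totals and the percent row can all be recomputed from them without any
gene-level data.  Trait means for the grain-yield heterosis worked example
are included alongside.
"""

from __future__ import annotations

import pandas as pd

from .io import DEFAULT_TISSUES

HYBRIDS = ("H1xH8", "T485xH8")

# per (hybrid, tissue): DEG2P, DEGP1, DEGP2, DEGFu-sp counts
_DEG_CELLS = {
    "H1xH8": {
        "0-L": (6257, 1465, 4874, 1162),
        "0-S": (4716, 1342, 3730, 1408),
        "0-P": (2409, 1534, 2205, 1548),
        "0-Z": (3615, 995, 2745, 1151),
        "5-L": (2120, 1131, 857, 521),
        "5-S": (4503, 3813, 3972, 3020),
        "5-P": (8489, 984, 6049, 1137),
        "5-Z": (3602, 1665, 3854, 1903),
    },
    "T485xH8": {
        "0-L": (6374, 5082, 1785, 1568),
        "0-S": (6309, 4131, 1485, 1232),
        "0-P": (3173, 1539, 1696, 961),
        "0-Z": (4872, 1849, 3707, 1591),
        "5-L": (2471, 1506, 1046, 762),
        "5-S": (3328, 1358, 2605, 1390),
        "5-P": (3882, 2902, 4320, 3141),
        "5-Z": (3364, 1603, 3064, 1550),
    },
}

# per (hybrid, tissue): non-additive DEGs, up- and down-regulated
_NDEG_CELLS = {
    "H1xH8": {
        "0-L": (62, 17),
        "0-S": (40, 15),
        "0-P": (48, 56),
        "0-Z": (86, 23),
        "5-L": (20, 4),
        "5-S": (86, 93),
        "5-P": (100, 80),
        "5-Z": (47, 65),
    },
    "T485xH8": {
        "0-L": (21, 27),
        "0-S": (41, 20),
        "0-P": (32, 7),
        "0-Z": (58, 19),
        "5-L": (7, 8),
        "5-S": (32, 35),
        "5-P": (63, 130),
        "5-Z": (23, 28),
    },
}

# grain yield per plant (g), mean over two seasons: T485, H8 and their F1
GRAIN_YIELD_T485XH8 = {"p1_mean": 5.14, "p2_mean": 10.89, "f1_mean": 18.72}

# tissue-type pooling: each physical tissue is sampled before (0-) and five
# days after (5-) flowering
TISSUE_TYPES = {
    "leaf": ("0-L", "5-L"),
    "sheath": ("0-S", "5-S"),
    "spikelet": ("0-P", "5-P"),
    "panicle_axis": ("0-Z", "5-Z"),
}


def deg_cells() -> pd.DataFrame:
    """Published DEG set sizes as a tidy table (hybrid, tissue, deg2p, degp1,
    degp2, degfu_sp)."""
    rows = [
        (h, t, *_DEG_CELLS[h][t]) for h in HYBRIDS for t in DEFAULT_TISSUES
    ]
    return pd.DataFrame(
        rows, columns=["hybrid", "tissue", "deg2p", "degp1", "degp2", "degfu_sp"]
    )


def ndeg_cells() -> pd.DataFrame:
    """Published non-additive DEG counts as a tidy table (hybrid, tissue, up, down)."""
    rows = [(h, t, *_NDEG_CELLS[h][t]) for h in HYBRIDS for t in DEFAULT_TISSUES]
    return pd.DataFrame(rows, columns=["hybrid", "tissue", "up", "down"])
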