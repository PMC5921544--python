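"""Packaged homology-map fixtures and the printed totals they reproduce."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .homology import HomologyMap, parse_homology_map

#: printed homologous-segment totals per (probe, target) map, and the
#: include_y setting that reproduces each.  The CBR->RPU entry is the one map
#: whose printed total (26) matches the enumerated signals (27) only after
#: dropping the Y-linked target; both conventions are reachable via the flag.
PRINTED_SEGMENT_COUNTS: dict[tuple[str, str], tuple[int, bool]] = {
    ("PHA", "RPU"): (17, True),
    ("CBR", "RPU"): (26, False),
    ("PHA", "RFI"): (24, True),
    ("CBR", "RFI"): (29, True),
    ("PHA", "TNI"): (21, True),
    ("CBR", "TNI"): (24, True),
    ("PHA", "GSO"): (18, True),
    ("CBR", "GSO"): (26, True),
}

_FILES = {
    ("PHA", "RPU"): "pha_rpu.tsv",
    ("CBR", "RPU"): "cbr_rpu.tsv",
    ("PHA", "RFI"): "pha_rfi.tsv",
    ("CBR", "RFI"): "cbr_rfi.tsv",
    ("PHA", "TNI"): "pha_tni.tsv",
    ("CBR", "TNI"): "cbr_tni.tsv",
    ("PHA", "GSO"): "pha_gso.tsv",
    ("CBR", "GSO"): "cbr_gso.tsv",
    ("PHA", "GSO-arms"): "pha_gso_arms_synthetic.tsv",
    ("HSA", "GSO"): "hsa_gso_synthetic.tsv",
}


def fixture_path(probe: str, target: str) -> Path:
    name = _FILES[(probe, target)]
    return Path(resources.files("paintphylo").joinpath("data", "maps", name))


def load_map(probe: str, target: str) -> HomologyMap:
    """Load a packaged homology map, e.g. ``load_map("PHA", "RPU")``."""
    return parse_homology_map(fixture_path(probe, target))


def all_painting_maps() -> dict[tuple[str, str], HomologyMap]:
    """The eight transcribed painting maps (excludes the synthetic HSA pair)."""
    return {key: load_map(*key) for key in PRINTED_SEGMENT_COUNTS}
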