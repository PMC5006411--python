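"""Bundled example data.

The Beitler & Landis eight-center infection trial: 273 subjects randomized
to an active drug or control, with cure rates varying from 0–86 % across
centers (intracenter correlation ≈ 0.22).  A standard worked example for
clustered binary data with a small number of clusters.
"""

from importlib import resources

from .data import CenterCountTable, TrialData, expand_counts, read_count_csv

__all__ = ["load_beitler_landis_counts", "load_beitler_landis"]


def load_beitler_landis_counts() -> CenterCountTable:
    """The eight-center trial as a per-center two-arm count table."""
    ref = resources.files("rdgee._data") / "beitler_landis_counts.csv"
    with resources.as_file(ref) as path:
        return read_count_csv(path)


def load_beitler_landis() -> TrialData:
    """The eight-center trial expanded to subject level (n=273, J=8)."""
    return expand_counts(load_beitler_landis_counts())
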