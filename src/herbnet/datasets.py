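"""Bundled reference data."""

from importlib import resources

import pandas as pd


def load_reference_metabolite_table() -> pd.DataFrame:
    """Curated reference screen of 47 differential metabolites.

    An untargeted UPLC-MS/MS comparison of formononetin-treated versus
    control HepG2 cells, with the reported VIP score, t-test p-value,
    fold change (treated mean over control mean) and trend per
    metabolite. Serves as a real-data fixture for the screening
    thresholds (VIP > 1, p < 0.05, two-sided fold change).

    Returns a DataFrame indexed by metabolite name with columns
    ``formula, mz, rt_min, hmdb, vip, p_value, fc, trend, mode``.
    """
    ref = resources.files("herbnet.data") / "hepg2_formononetin_metabolites.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return table.set_index("metabolite")
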