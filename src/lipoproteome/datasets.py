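"""Bundled reference result tables for replay-style validation.

Two small published result tables ship with the package:

* ``lpa_ldl_enrichment.tsv`` — per-protein Lp(a)/LDL enrichment ratios and
  paired-test P values from a discovery and a replication phase, used to
  replay the cross-phase replication rule.
* ``mr_screen_results.tsv`` — IVW-MR effect estimates (beta, SE, P) of
  plasma proteins screened against lifelong Lp(a) and LDL-cholesterol
  exposure, used to replay the Bonferroni significance call.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_enrichment_reference", "load_mr_reference"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("lipoproteome.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_enrichment_reference() -> pd.DataFrame:
    """Discovery/replication enrichment table, indexed by gene symbol."""
    return _read("lpa_ldl_enrichment.tsv").set_index("gene")


def load_mr_reference() -> pd.DataFrame:
    """MR screen reference results with an ``exposure`` column (LPA/LDL)."""
    return _read("mr_screen_results.tsv")
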