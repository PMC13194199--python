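"""Bundled published-table fixtures for the niacinamide serum/cream study.

Two paired-result tables (image-photometry candidate vs HPLC reference,
with product labels where declared) and the nine 1:9 ... 9:1 equal-molarity
volume ratios of the continuous-variation experiment.  These are small
printed input tables, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stoichiometry import job_mixture_fractions

__all__ = [
    "load_serum_cream_results",
    "load_spe_results",
    "load_comparison_pairs",
    "load_job_mixture_fractions",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("platequant.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_serum_cream_results() -> pd.DataFrame:
    """Ten serum/cream samples quantified without cleanup (candidate vs HPLC)."""
    return _read("comparison_table2.csv")


def load_spe_results() -> pd.DataFrame:
    """Three serums re-quantified after solid-phase extraction cleanup."""
    return _read("comparison_table3.csv")


def load_comparison_pairs() -> pd.DataFrame:
    """The ten pairs entering the method-comparison statistics.

    All direct-analysis samples except Oly — whose matrix interferes with
    the colorimetric reagent — plus Oly's post-cleanup result.
    """
    t2 = load_serum_cream_results()
    t3 = load_spe_results()
    pairs = pd.concat(
        [t2[t2["sample_id"] != "Oly"], t3[t3["sample_id"] == "Oly"]],
        ignore_index=True,
    )
    return pairs


def load_job_mixture_fractions() -> np.ndarray:
    """Ligand mole fractions 0.1 ... 0.9 of the nine bundled mixtures."""
    df = _read("job_mixtures.csv")
    return job_mixture_fractions(df["ligand_volume_ml"], df["metal_volume_ml"])
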