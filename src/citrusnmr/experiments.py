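"""Reference in-silico experiments built from the pipeline stages.

These are the package's standing simulation studies: replicate
repeatability of the sweetness/acid ratio, and cross-field equivalence
of end-to-end ratios.  Both run the generator -> processing ->
quantification -> scoring chain from scratch for a given seed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import score_cohort
from .processing import ProcessingParams, process_fid
from .quantify import default_windows, relative_areas
from .scoring import SweetnessWeights, sweetness_acid_ratio
from .simulate import (
    composition_for_ratio,
    default_citrate_offset,
    simulate_cohort,
    synthesize_fid,
)
from .types import BENCHTOP_SCHEME, HIGH_FIELD_SCHEME

__all__ = [
    "DEFAULT_TARGET_RATIOS",
    "replicate_rsd_study",
    "field_equivalence_study",
]

#: Target sweetness/acid ratios of the five-variety study cohort,
#: spanning the range observed across mandarin varieties (about 4-12).
DEFAULT_TARGET_RATIOS = (9.31, 10.12, 7.70, 6.34, 4.16)


def _variety_table(target_ratios: Sequence[float]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variety_id": [f"V{i+1}" for i in range(len(target_ratios))],
            "target_ratio": list(target_ratios),
        }
    )


def replicate_rsd_study(
    seed: int,
    target_ratios: Sequence[float] = DEFAULT_TARGET_RATIOS,
    n_replicates: int = 5,
    params: Optional[ProcessingParams] = None,
) -> pd.Series:
    """Per-variety RSD (%) of the ratio over simulated replicates.

    Simulates the cohort at the high-field scheme with default replicate
    variability and noise, runs the full processing/quantification/
    scoring chain, and returns the per-variety relative standard
    deviation of the sweetness/acid ratio.
    """
    fids = simulate_cohort(
        _variety_table(target_ratios), n_replicates, HIGH_FIELD_SCHEME, seed=seed
    )
    params = params or ProcessingParams()
    scored = score_cohort(fids, params, default_windows("high_field"), SweetnessWeights())
    return scored.groupby("variety_id")["ratio"].apply(
        lambda r: float(100.0 * r.std(ddof=1) / r.mean())
    )


def field_equivalence_study(
    seed: int,
    target_ratios: Sequence[float] = DEFAULT_TARGET_RATIOS,
    params: Optional[ProcessingParams] = None,
) -> pd.DataFrame:
    """End-to-end ratios of single samples under both acquisition schemes.

    Each composition is synthesized, processed and quantified once per
    instrument (with the field-appropriate citrate position and
    integration window).  Returns a DataFrame with columns
    ``target_ratio``, ``ratio_high_field``, ``ratio_benchtop`` and
    ``relative_difference``.
    """
    params = params or ProcessingParams()
    rng = np.random.default_rng(seed)
    rows = []
    for i, target in enumerate(target_ratios):
        sample_seed = int(rng.integers(0, 2**31 - 1))
        ratios = {}
        for tag, scheme in (("high_field", HIGH_FIELD_SCHEME), ("benchtop", BENCHTOP_SCHEME)):
            comp = dataclasses.replace(
                composition_for_ratio(target),
                citrate_center_offset=default_citrate_offset(scheme),
            )
            fid = synthesize_fid(
                comp, scheme, seed=sample_seed, sample_id=f"S{i+1}_{tag}"
            )
            spec = process_fid(fid, params)
            areas = relative_areas(spec, default_windows(tag))
            ratios[tag] = sweetness_acid_ratio(areas)
        rows.append(
            {
                "target_ratio": target,
                "ratio_high_field": ratios["high_field"],
                "ratio_benchtop": ratios["benchtop"],
                "relative_difference": abs(ratios["benchtop"] - ratios["high_field"])
                / ratios["high_field"],
            }
        )
    return pd.DataFrame(rows)
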