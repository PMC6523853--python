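"""Background-referenced combination test and replicate-overlap similarity.

The combination test references every bait replicate against every background
(control) replicate: with 3 sample and 3 control replicates each protein gets
9 combination values, with 4x3 it gets 12. In ``ratio`` mode the value is
sample/control on the normalised intensity scale; in ``log2diff`` mode it is
the difference of log2 values. The per-protein median of these combinations
is the background-referenced affinity used by all downstream stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import DataError

logger = logging.getLogger(__name__)

COMBINATION_MODES = ("ratio", "log2diff")


@dataclass
class CombinationSet:
    """All sample x control replicate-pair values, one row per protein.

    ``values`` columns are a (sample_replicate, control_replicate) MultiIndex;
    cells are NaN where either side was missing under the ``drop`` policy.
    Proteins missing from every sample replicate are excluded at construction.
    """

    condition: str
    values: pd.DataFrame
    mode: str

    def n_pairs(self) -> int:
        return self.values.shape[1]

    def median(self) -> pd.Series:
        return median_combination(self)


def combination_values(sample: pd.DataFrame, control: pd.DataFrame,
                       mode: str, condition: str = "") -> CombinationSet:
    """Enumerate all ordered sample x control replicate pairs per protein.

    ``sample`` and ``control`` are replicate sub-matrices sharing an accession
    index (aligned by intersection). ``ratio`` mode computes s/c and requires
    strictly positive control values; ``log2diff`` computes s - c on log2
    values. NaN on either side yields a NaN pair value (``drop`` policy);
    proteins with no finite sample value at all are dropped from the set.
    """
    if mode not in COMBINATION_MODES:
        raise DataError(f"unknown combination mode {mode!r}")
    common = sample.index.intersection(control.index)
    if len(common) < len(sample.index):
        logger.info("combination_values[%s]: %d proteins absent from control side",
                    condition, len(sample.index) - len(common))
    s = sample.loc[common].to_numpy(dtype=float)
    c = control.loc[common].to_numpy(dtype=float)
    if mode == "ratio":
        if np.any(c[np.isfinite(c)] <= 0):
            raise DataError("ratio mode requires positive control values; "
                            "apply a zero policy first")
        pairs = s[:, :, None] / c[:, None, :]
    else:
        pairs = s[:, :, None] - c[:, None, :]
    n_s, n_c = s.shape[1], c.shape[1]
    cols = pd.MultiIndex.from_product(
        [sample.columns, control.columns], names=["sample_replicate", "control_replicate"])
    df = pd.DataFrame(pairs.reshape(len(common), n_s * n_c), index=common, columns=cols)

    # A protein absent from every sample replicate carries no evidence for
    # this condition; drop it from the set.
    sample_absent = ~np.isfinite(s).any(axis=1)
    if sample_absent.any():
        logger.info("combination_values[%s]: dropping %d proteins absent on the sample side",
                    condition, int(sample_absent.sum()))
        df = df.loc[~sample_absent]
    return CombinationSet(condition=condition, values=df, mode=mode)


def median_combination(cs: CombinationSet) -> pd.Series:
    """Per-protein median of the combination values (NaN pairs ignored).

    Proteins whose combination vector is entirely missing are returned as
    NaN, the absent-protein signal for downstream alignment.
    """
    if cs.values.shape[1] == 0:
        raise DataError("empty combination set")
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(cs.values.to_numpy(), axis=1)
    return pd.Series(med, index=cs.values.index, name=f"median_{cs.condition}")


def replicate_overlap(replicates: pd.DataFrame, method: str = "allway") -> float:
    """Percentage overlap of the per-replicate detection sets.

    Detection is a strictly positive value. ``allway`` (default) is
    intersection over union across all replicates; ``pairwise`` averages the
    Jaccard index over all replicate pairs.
    """
    if replicates.shape[1] < 2:
        raise DataError("replicate_overlap requires at least 2 replicates")
    detected = [set(replicates.index[replicates.iloc[:, j] > 0])
                for j in range(replicates.shape[1])]
    if method == "allway":
        union = set.union(*detected)
        if not union:
            return 0.0
        inter = set.intersection(*detected)
        return 100.0 * len(inter) / len(union)
    if method == "pairwise":
        vals = []
        for i in range(len(detected)):
            for j in range(i + 1, len(detected)):
                u = detected[i] | detected[j]
                vals.append(len(detected[i] & detected[j]) / len(u) if u else 0.0)
        return 100.0 * float(np.mean(vals))
    raise DataError(f"unknown overlap method {method!r}")
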