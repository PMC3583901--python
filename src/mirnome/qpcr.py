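"""qPCR companion arithmetic: 2^-ddCt quantification and reads-Ct correlation.

Relative quantification follows the comparative Ct method: the target Ct
is normalised to an endogenous control (U6/RNU6B) within each sample
(dCt), referenced to the mean dCt of the designated control samples
(ddCt), and expressed as 2^-ddCt so the reference maps to 1.0.

The reads-vs-Ct correlation underpins the use of cloning frequency as an
abundance proxy: Pearson correlation between log10(read count) and the
qPCR Ct value, with the p-value from the t distribution with n-2 degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QPCRMeasurement", "CorrelationResult", "delta_delta_ct",
           "reads_ct_correlation", "read_ct_table"]


@dataclass
class QPCRMeasurement:
    sample_id: str
    group: str
    target_ct: float
    control_ct: float
    is_reference_sample: bool = False


@dataclass
class CorrelationResult:
    n: int
    r_squared: float
    p_value: float


def _as_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements.copy()
    return pd.DataFrame([m.__dict__ for m in measurements])


def delta_delta_ct(measurements) -> pd.DataFrame:
    """Per-sample relative quantity 2^-ddCt.

    ``measurements`` is a DataFrame (columns sample_id, group, target_ct,
    control_ct, is_reference_sample) or a list of QPCRMeasurement.  ddCt
    is referenced to the mean dCt over all reference samples, whose mean
    relative quantity is therefore 2^0 = 1 up to their spread.
    """
    df = _as_frame(measurements)
    if "is_reference_sample" not in df or not df["is_reference_sample"].any():
        raise ValueError("at least one reference (control) sample is required")
    if not np.isfinite(df[["target_ct", "control_ct"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    df["delta_ct"] = df["target_ct"] - df["control_ct"]
    ref = df.loc[df["is_reference_sample"], "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - ref
    df["rel_quantity"] = 2.0 ** (-df["delta_delta_ct"])
    return df


def reads_ct_correlation(reads, ct, already_log: bool = False
                         ) -> CorrelationResult:
    """Pearson correlation of (log10 reads, Ct) pairs.

    ``already_log`` skips the log10 transform when the read values are
    pre-transformed.  Requires n >= 3 and non-zero variance in both
    variables.
    """
    x = np.asarray(reads, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired (reads, Ct) observations")
    if not already_log:
        if np.any(x <= 0):
            raise ValueError("read counts must be positive for log10")
        x = np.log10(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in one variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(n=len(x), r_squared=float(r * r), p_value=float(p))


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns sample_id, group, target_ct, control_ct,
    is_reference_sample."""
    df = pd.read_csv(path, sep="\t")
    df["is_reference_sample"] = df["is_reference_sample"].astype(bool)
    return df
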