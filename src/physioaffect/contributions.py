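"""Signed input-contribution analysis for single-hidden-layer networks.

For each output unit, the influence of input ``i`` routed through hidden
unit ``j`` is the signed share of that hidden unit's input weights,
``w_ji / sum_i' |w_ji'|``, scaled by the hidden-to-output weight ``w_oj``.
Summing over hidden units and re-normalizing by the total absolute
contribution yields a signed proportion per input whose absolute values sum
to 1 for each output.  Unlike magnitude-only connection-weight methods,
the sign survives, so a negative contribution means the feature is higher
when the output is lower (e.g. corrugator activity for negative valence).

Contribution sizes across the ensemble's trials are compared with a one-way
repeated-measures ANOVA (trials as subjects, feature as the within factor,
uncorrected degrees of freedom), and summarized against the null threshold
1/n_inputs — the share each feature would have if all contributed equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from .errors import ModelError
from .features import FEATURES
from .mlp import MLPWeights

OUTPUTS = ("valence", "arousal")

#: contribution magnitude under equal sharing among the 5 inputs
NULL_THRESHOLD = 1.0 / len(FEATURES)


def milne_contributions(weights: MLPWeights,
                        input_names: tuple[str, ...] = FEATURES,
                        output_names: tuple[str, ...] = OUTPUTS) -> pd.DataFrame:
    """Signed, normalized contribution of each input to each output.

    Biases are excluded: contributions partition the influence carried by
    input-connected weights.  Returns a DataFrame (inputs x outputs) whose
    per-column absolute sums are 1.
    """
    W_hi = np.asarray(weights.W_hi, dtype=float)   # (H, I)
    W_oh = np.asarray(weights.W_oh, dtype=float)   # (O, H)
    row_abs = np.abs(W_hi).sum(axis=1)
    if np.any(row_abs == 0):
        j = int(np.argmax(row_abs == 0))
        raise ModelError(f"hidden unit {j} has all-zero input weights")
    shares = W_hi / row_abs[:, None]               # (H, I) signed input shares
    raw = W_oh @ shares                            # (O, I)
    denom = np.abs(raw).sum(axis=1)
    if np.any(denom == 0):
        o = int(np.argmax(denom == 0))
        raise ModelError(f"all contributions vanish for output {o}: undefined")
    c = (raw / denom[:, None]).T                   # (I, O)
    return pd.DataFrame(c, index=list(input_names)[: W_hi.shape[1]],
                        columns=list(output_names)[: W_oh.shape[0]])


def ensemble_contributions(weight_sets: list[MLPWeights]) -> dict[str, pd.DataFrame]:
    """Per-trial signed contributions for each output: DataFrames of shape
    (n_trials, n_features) keyed by output name."""
    per_trial = [milne_contributions(w) for w in weight_sets]
    out = {}
    for o in OUTPUTS:
        out[o] = pd.DataFrame([c[o].to_numpy() for c in per_trial], columns=list(FEATURES))
    return out


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def rm_anova(contribution_sizes: np.ndarray | pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA on a trials x features matrix of
    contribution sizes (|c|), trials as subjects, no sphericity correction."""
    M = np.asarray(contribution_sizes, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ModelError("need a trials x features matrix with >= 2 of each")
    if np.isnan(M).any():
        raise ModelError("missing cells in the contribution matrix")
    n, k = M.shape
    # residual SS must be positive for F to exist
    cell = M - M.mean(axis=1, keepdims=True) - M.mean(axis=0, keepdims=True) + M.mean()
    ss_err = float((cell ** 2).sum())
    if ss_err == 0:
        raise ModelError("zero error sum of squares: F undefined")
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "feature": np.tile(np.arange(k), n),
        "value": M.ravel(),
    })
    res = AnovaRM(long, depvar="value", subject="subject", within=["feature"]).fit()
    row = res.anova_table.iloc[0]
    return AnovaResult(F=float(row["F Value"]), df1=int(row["Num DF"]),
                       df2=int(row["Den DF"]), p=float(row["Pr > F"]))


def threshold_report(matrix: pd.DataFrame, threshold: float = NULL_THRESHOLD
                     ) -> dict[str, list[tuple[str, int]]]:
    """Per output, the features whose |contribution| strictly exceeds the null
    threshold, ordered by |c| descending, with their signs (+1/-1)."""
    report: dict[str, list[tuple[str, int]]] = {}
    for o in matrix.columns:
        col = matrix[o]
        above = col[col.abs() > threshold]
        ordered = above.reindex(above.abs().sort_values(ascending=False).index)
        report[o] = [(f, 1 if v > 0 else -1) for f, v in ordered.items()]
    return report
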