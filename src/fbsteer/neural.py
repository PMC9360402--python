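"""Neural-response quantification and decoding.

Works on tidy response tables (columns ``fly, trial, direction, phase,
response``) holding one scalar per trial and stimulus phase -- a windowed
mean Delta-F/F for imaging or a firing rate for electrophysiology.  Wind
directions come from the five-direction stimulus set {-90, -45, 0, +45,
+90} (degrees, egocentric; negative = fly's left).

Provides Delta-F/F normalization, the responsive-column criterion
(response > baseline mean + 2 SD), a one-way ANOVA for direction tuning of
pooled trials, and cross-validated classification-tree decoding (wind
direction pooled into left/center/right, or odor-vs-wind and
odor-vs-baseline phase discrimination) against a shuffled-label null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

__all__ = ["DecodeResult", "dff", "responsive_columns", "direction_anova",
           "decode_direction", "decode_condition", "pool_direction"]

DIRECTIONS = (-90.0, -45.0, 0.0, 45.0, 90.0)
PHASES = ("baseline", "wind_on", "odor", "odor_off", "wind_off")


# --------------------------------------------------------------------------
# response quantification
# --------------------------------------------------------------------------

def dff(trace, fs: float, baseline_s: float = 5.0, skip_first: int = 1,
        subtract_one: bool = False) -> np.ndarray:
    """Fluorescence trace normalized by its baseline-period mean.

    The baseline is the first ``baseline_s`` seconds of the trial
    excluding the first ``skip_first`` samples (shutter lag).  By default
    the result is fold-of-baseline; ``subtract_one`` reports the
    conventional (F - F0)/F0 instead.
    """
    trace = np.asarray(trace, dtype=float)
    n_base = int(round(baseline_s * fs))
    base = trace[skip_first:n_base]
    if base.size == 0:
        raise ValueError("baseline window contains no samples")
    f0 = base.mean()
    if f0 <= 0:
        raise ValueError("nonpositive baseline fluorescence")
    out = trace / f0
    return out - 1.0 if subtract_one else out


def responsive_columns(responses: pd.DataFrame, phase: str = "odor",
                       baseline_phase: str = "baseline",
                       group: str = "column", n_std: float = 2.0) -> list:
    """Groups (e.g. FB columns) responding above baseline mean + 2 SD.

    For each group, compares the mean response in ``phase`` against the
    mean + ``n_std`` * SD of its ``baseline_phase`` responses.  Groups
    whose baseline variance is zero are skipped with a warning.
    """
    import warnings

    out = []
    for key, g in responses.groupby(group):
        base = g.loc[g["phase"] == baseline_phase, "response"]
        resp = g.loc[g["phase"] == phase, "response"]
        if base.empty or resp.empty:
            continue
        sd = base.std(ddof=1) if len(base) > 1 else 0.0
        if not sd > 0:
            warnings.warn(f"zero-variance baseline for {group}={key!r}; skipped")
            continue
        if resp.mean() > base.mean() + n_std * sd:
            out.append(key)
    return out


def direction_anova(responses: pd.DataFrame, phase: str = "odor"):
    """One-way ANOVA of responses across directions, trials pooled over flies.

    Returns ``(F, p)``.  Requires at least two directions with two or more
    trials each.
    """
    sel = responses[responses["phase"] == phase]
    groups = [g["response"].to_numpy() for _, g in sel.groupby("direction")]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 directions with >= 2 trials for ANOVA")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# decoding
# --------------------------------------------------------------------------

@dataclass
class DecodeResult:
    """Cross-validated decoding performance against a shuffled-label null."""

    cv_error: float
    shuffled_errors: np.ndarray
    p_value: float
    classes: tuple
    task: str
    n_folds: int
    n_shuffles: int
    metadata: dict = field(default_factory=dict)

    @property
    def shuffled_mean(self) -> float:
        return float(np.mean(self.shuffled_errors))


def pool_direction(direction) -> str:
    """Pool the five stimulus directions into left / center / right."""
    d = float(direction)
    if d < 0:
        return "left"
    if d > 0:
        return "right"
    return "center"


def _zscore_within_fly(df: pd.DataFrame) -> np.ndarray:
    z = np.empty(len(df))
    for _, idx in df.groupby("fly").indices.items():
        v = df["response"].to_numpy()[idx]
        sd = v.std(ddof=0)
        z[idx] = (v - v.mean()) / sd if sd > 0 else 0.0
    return z


def _decode(df: pd.DataFrame, labels: np.ndarray, task: str, n_folds: int,
            n_shuffles: int, seed: int, zscore: str) -> DecodeResult:
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("decoding requires at least two classes")
    counts = pd.Series(labels).value_counts()
    if counts.min() < n_folds:
        n_folds = int(counts.min())
        if n_folds < 2:
            raise ValueError("too few trials per class for cross-validation")
    if zscore == "per_fly":
        z = _zscore_within_fly(df)
    elif zscore == "pooled":
        v = df["response"].to_numpy()
        z = (v - v.mean()) / v.std(ddof=0)
    else:
        raise ValueError("zscore must be 'per_fly' or 'pooled'")
    fly_codes = pd.Categorical(df["fly"]).codes.astype(float)
    X = np.column_stack([fly_codes, z])

    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                         random_state=int(rng.integers(2**31)))
    tree = DecisionTreeClassifier(random_state=int(rng.integers(2**31)))
    err = 1.0 - cross_val_score(tree, X, labels, cv=cv).mean()
    shuffled = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(labels)
        cv_i = StratifiedKFold(n_splits=n_folds, shuffle=True,
                               random_state=int(rng.integers(2**31)))
        shuffled[i] = 1.0 - cross_val_score(tree, X, perm, cv=cv_i).mean()
    # two-sided permutation p-value of the observed error under the null
    n_le = int(np.sum(shuffled <= err))
    n_ge = int(np.sum(shuffled >= err))
    p = min(1.0, 2.0 * (1 + min(n_le, n_ge)) / (n_shuffles + 1))
    return DecodeResult(
        cv_error=float(err), shuffled_errors=shuffled, p_value=float(p),
        classes=classes, task=task, n_folds=n_folds, n_shuffles=n_shuffles,
        metadata={"seed": seed, "zscore": zscore,
                  "tree": "impurity-based binary tree, unlimited depth, "
                          "min leaf 1", "predictors": ["fly", "zscore"]})


def decode_direction(responses: pd.DataFrame, phase: str = "odor",
                     n_folds: int = 10, n_shuffles: int = 50, seed: int = 0,
                     zscore: str = "per_fly") -> DecodeResult:
    """Decode wind side (left/center/right) from single-trial responses.

    Trials at 45 and 90 degrees on each side are pooled.  A classification
    tree with predictors (fly identity, within-fly Z-scored response) is
    scored by stratified ``n_folds``-fold cross-validation error and
    compared against ``n_shuffles`` label-shuffled fits via a two-sided
    permutation p-value.
    """
    sel = responses[responses["phase"] == phase].reset_index(drop=True)
    if sel.empty:
        raise ValueError(f"no trials for phase {phase!r}")
    labels = sel["direction"].map(pool_direction).to_numpy()
    return _decode(sel, labels, f"direction@{phase}", n_folds, n_shuffles,
                   seed, zscore)


def decode_condition(responses: pd.DataFrame, classes=("odor", "wind_on"),
                     n_folds: int = 10, n_shuffles: int = 50, seed: int = 0,
                     zscore: str = "per_fly") -> DecodeResult:
    """Decode stimulus phase (e.g. odor vs wind, odor vs baseline).

    Data are pooled across all wind directions; otherwise identical to
    :func:`decode_direction`.
    """
    sel = responses[responses["phase"].isin(classes)].reset_index(drop=True)
    present = set(sel["phase"])
    if present != set(classes):
        raise ValueError(f"missing phase(s): {set(classes) - present}")
    labels = sel["phase"].to_numpy()
    return _decode(sel, labels, "vs".join(classes), n_folds, n_shuffles,
                   seed, zscore)
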