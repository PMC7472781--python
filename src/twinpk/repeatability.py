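"""Within/between-subject variance decomposition and the repeated-dosing
"genetic component" statistic.

For a trait measured on several occasions per subject, the within-subject
variance Var_w is the pooled per-subject sample variance and the
between-subject variance Var_b is the sample variance of subject means.
The genetic component rGC = (Var_b - Var_w) / Var_b is an upper bound on
heritability: it cannot separate genetic effects from environmental
factors that are constant within a subject.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


class RepeatabilityError(ValueError):
    pass


@dataclass
class RepeatabilityResult:
    trait: str
    mean: float
    var_within: float
    var_between: float
    r_gc: float
    n_subjects: int
    n_occasions_mean: float


def within_between_variance(values: pd.DataFrame,
                            subject_col: str = "subject_id",
                            value_col: str = "value",
                            correct_between: bool = False) -> tuple[float, float, float]:
    """Pooled within-subject and between-subject variance of replicates.

    ``values`` holds one row per subject x occasion.  Var_w pools the
    per-subject sample variances weighted by their degrees of freedom;
    Var_b is the sample variance of the subject means.  With
    ``correct_between`` the occasion-sampling contribution Var_w/k_bar is
    subtracted from Var_b (floored at zero); the plain subject-mean
    variance is the default.
    """
    groups = values.groupby(subject_col)[value_col]
    n_subj = groups.ngroups
    if n_subj < 2:
        raise RepeatabilityError("need at least 2 subjects")
    counts = groups.count()
    if (counts < 2).all():
        raise RepeatabilityError("within variance undefined: no subject has replicate occasions")
    ss_within = 0.0
    df_within = 0
    for _, g in groups:
        k = len(g)
        if k >= 2:
            ss_within += float(np.sum((g - g.mean()) ** 2))
            df_within += k - 1
    var_w = ss_within / df_within
    means = groups.mean()
    var_b = float(np.var(means, ddof=1))
    if correct_between:
        var_b = max(var_b - var_w / counts.mean(), 0.0)
    return var_w, var_b, float(means.mean())


def genetic_component(var_w: float, var_b: float) -> float:
    """rGC = (Var_b - Var_w) / Var_b.

    Negative values (within-subject variance exceeding between-subject
    variance) are reported as computed.
    """
    if var_b <= 0:
        raise RepeatabilityError("genetic component undefined: between-subject variance is zero")
    return (var_b - var_w) / var_b


def repeatability_table(long_df: pd.DataFrame,
                        trait_col: str = "trait",
                        value_col: str = "value",
                        subject_col: str = "subject_id",
                        correct_between: bool = False) -> pd.DataFrame:
    """RepeatabilityResult per trait from a long subject x occasion table."""
    rows = []
    for trait, grp in long_df.groupby(trait_col, sort=False):
        var_w, var_b, mean = within_between_variance(
            grp, subject_col=subject_col, value_col=value_col,
            correct_between=correct_between)
        rows.append(asdict(RepeatabilityResult(
            trait=trait, mean=mean, var_within=var_w, var_between=var_b,
            r_gc=genetic_component(var_w, var_b),
            n_subjects=grp[subject_col].nunique(),
            n_occasions_mean=float(grp.groupby(subject_col)[value_col].count().mean()),
        )))
    return pd.DataFrame(rows)


def bootstrap_r_gc(values: pd.DataFrame, n_boot: int = 1000,
                   subject_col: str = "subject_id", value_col: str = "value",
                   seed: int = 0) -> np.ndarray:
    """Subject-resampling bootstrap distribution of rGC."""
    rng = np.random.default_rng(seed)
    subjects = values[subject_col].unique()
    grouped = {s: g[value_col].to_numpy() for s, g in values.groupby(subject_col)}
    out = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        frames = [pd.DataFrame({subject_col: f"{s}_{i}", value_col: grouped[s]})
                  for i, s in enumerate(pick)]
        df = pd.concat(frames, ignore_index=True)
        var_w, var_b, _ = within_between_variance(df, subject_col, value_col)
        out[b] = genetic_component(var_w, var_b)
    return out
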