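"""Agreement statistics: precision, repeated-measures Bland-Altman, MPE.

Implements the study's statistical surface for comparing a test method
against a reference on paired measurements collected repeatedly in the
same subjects:

* precision = 1.96 × coefficient of variation of repeated measurements;
* Bland-Altman limits of agreement compensated for repeated measures
  ("multiple observations per individual, true value varies"): the
  variance of a single inter-method difference is decomposed by one-way
  analysis of variance of the differences by subject into a
  between-subject and a within-subject component;
* mean percentage error (Critchley): 1.96·SD of the differences divided
  by the mean of the reference method, conventionally < 30 % for
  clinical interchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

MPE_ACCEPTABILITY_PCT = 30.0


@dataclass(frozen=True)
class PrecisionResult:
    mean: float
    sd: float
    cv: float
    precision_pct: float  # 1.96 * cv * 100


@dataclass(frozen=True)
class AgreementSummary:
    bias: float
    uloa: float
    lloa: float
    sd_diff: float
    ci_bias: tuple[float, float]
    ci_uloa: tuple[float, float]
    ci_lloa: tuple[float, float]
    mpe_pct: float
    mean_ref: float
    n_pairs: int
    n_subjects: int
    acceptable: bool  # MPE below the a-priori 30 % threshold

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("ci_bias", "ci_uloa", "ci_lloa"):
            d[k] = list(d[k])
        return d


def precision_cv(repeats) -> PrecisionResult:
    """Precision of a method from >= 2 repeated measurements.

    Sample SD (n−1 denominator); CV = SD/mean; precision = 1.96·CV in %.
    """
    x = np.asarray(repeats, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 repeated measurements")
    if np.any(x <= 0):
        raise ValueError("repeated measurements must be positive")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = sd / mean
    return PrecisionResult(mean=mean, sd=sd, cv=cv, precision_pct=1.96 * cv * 100.0)


def mean_percentage_error(uloa: float, lloa: float, mean_ref: float,
                          bias: float | None = None) -> float:
    """Critchley MPE in percent: 100·((ULOA − LLOA)/2)/mean_ref.

    The limits are treated as an unordered pair (published tables
    occasionally swap the labels); ``bias`` is accepted for signature
    symmetry with agreement tables but does not enter the half-range.
    """
    if mean_ref <= 0:
        raise ValueError("mean_ref must be positive")
    return 100.0 * abs(uloa - lloa) / 2.0 / mean_ref


def bland_altman_rm(pairs: pd.DataFrame, *, test_col: str = "test_mlkg",
                    ref_col: str = "ref_mlkg",
                    subject_col: str = "subject_id") -> AgreementSummary:
    """Bland-Altman agreement compensated for repeated measures.

    With one pair per subject this reduces exactly to the classic
    analysis (SD of the differences).  With repeats, one-way ANOVA of
    the differences by subject gives mean squares MSB/MSW and the
    variance of a single difference is

        SD_diff² = (MSB − MSW)/m0 + MSW

    (m0 the usual balanced-design averaged group size; the between
    component is floored at zero).  95 % CIs use SE(bias) from the
    between-subject mean square (the differences within a subject are
    correlated) and SE(limit) = √3·SE(bias).
    """
    df = pairs[[subject_col, test_col, ref_col]].dropna()
    if df.empty:
        raise ValueError("no complete pairs")
    dropped = set(pairs[subject_col].unique()) - set(df[subject_col].unique())
    if dropped:
        import warnings

        warnings.warn(f"subjects {sorted(dropped)} excluded: all pairs missing")
    groups = df.groupby(subject_col)
    k = groups.ngroups
    if k < 2:
        raise ValueError("need >= 2 subjects")
    d = (df[test_col] - df[ref_col]).to_numpy(dtype=float)
    n = d.size
    bias = float(d.mean())
    sizes = groups.size().to_numpy(dtype=float)

    if sizes.max() == 1:
        # classic Bland-Altman
        sd_diff = float(d.std(ddof=1))
        se_bias = sd_diff / np.sqrt(n)
    else:
        dd = df.assign(_d=df[test_col] - df[ref_col])
        means = dd.groupby(subject_col)["_d"].mean().to_numpy()
        ssb = float(np.sum(sizes * (means - bias) ** 2))
        ssw = float(
            dd.groupby(subject_col)["_d"]
            .apply(lambda g: np.sum((g - g.mean()) ** 2))
            .sum()
        )
        msb = ssb / (k - 1)
        msw = ssw / (n - k) if n > k else 0.0
        m0 = (n - np.sum(sizes**2) / n) / (k - 1)
        var_between = max((msb - msw) / m0, 0.0)
        sd_diff = float(np.sqrt(var_between + msw))
        se_bias = float(np.sqrt(var_between / k + msw / n))

    uloa = bias + 1.96 * sd_diff
    lloa = bias - 1.96 * sd_diff
    se_loa = np.sqrt(3.0) * se_bias
    mean_ref = float(df[ref_col].mean())
    mpe = mean_percentage_error(uloa, lloa, mean_ref, bias)
    return AgreementSummary(
        bias=bias, uloa=uloa, lloa=lloa, sd_diff=sd_diff,
        ci_bias=(bias - 1.96 * se_bias, bias + 1.96 * se_bias),
        ci_uloa=(uloa - 1.96 * se_loa, uloa + 1.96 * se_loa),
        ci_lloa=(lloa - 1.96 * se_loa, lloa + 1.96 * se_loa),
        mpe_pct=mpe, mean_ref=mean_ref, n_pairs=n, n_subjects=k,
        acceptable=mpe < MPE_ACCEPTABILITY_PCT,
    )


def reproduce_agreement_tables(paired: pd.DataFrame, *,
                               step_col: str = "step_id",
                               test_col: str = "test_mlkg",
                               ref_col: str = "ref_mlkg",
                               subject_col: str = "subject_id"
                               ) -> tuple[AgreementSummary, pd.DataFrame]:
    """Pooled repeated-measures agreement plus a per-step table.

    Per step the design is one pair per subject, so each row is a
    classic Bland-Altman analysis of that step's differences.  The
    pooled summary also reports the MPE computed against the mean of the
    per-step reference means (``mpe_step_mean_ref_pct`` column on the
    pooled row) alongside the grand-mean version, since either pooling
    convention is defensible.
    """
    pooled = bland_altman_rm(
        paired, test_col=test_col, ref_col=ref_col, subject_col=subject_col
    )
    rows = []
    step_ref_means = []
    for step, sub in paired.groupby(step_col):
        if sub[[test_col, ref_col]].dropna().empty:
            import warnings

            warnings.warn(f"step {step}: no complete pairs, row omitted")
            continue
        s = bland_altman_rm(
            sub, test_col=test_col, ref_col=ref_col, subject_col=subject_col
        )
        step_ref_means.append(s.mean_ref)
        rows.append({
            "step_id": step, "n_pairs": s.n_pairs,
            "mean_test": float(sub[test_col].mean()),
            "mean_ref": s.mean_ref,
            "bias": s.bias, "uloa": s.uloa, "lloa": s.lloa,
            "ci_uloa_lo": s.ci_uloa[0], "ci_uloa_hi": s.ci_uloa[1],
            "ci_lloa_lo": s.ci_lloa[0], "ci_lloa_hi": s.ci_lloa[1],
            "mpe_pct": s.mpe_pct,
        })
    per_step = pd.DataFrame(rows)
    if step_ref_means:
        per_step.attrs["pooled_mpe_step_mean_ref_pct"] = mean_percentage_error(
            pooled.uloa, pooled.lloa, float(np.mean(step_ref_means))
        )
    return pooled, per_step


def render_table(per_step: pd.DataFrame) -> pd.DataFrame:
    """Report-style rounding: one decimal for bias/limits, integer MPE."""
    out = per_step.copy()
    for c in ("mean_test", "mean_ref", "bias", "uloa", "lloa",
              "ci_uloa_lo", "ci_uloa_hi", "ci_lloa_lo", "ci_lloa_hi"):
        out[c] = out[c].round(1)
    out["mpe_pct"] = out["mpe_pct"].round(0).astype(int)
    return out
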