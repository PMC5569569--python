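"""End-to-end method-comparison pipeline and its statistical analysis.

The study design mirrors a standard multi-subject EMG decomposition
comparison: every recording (one per subject x exercise program) is
decomposed with each method (EEMD channel-by-channel, MEMD and NA-MEMD
jointly across channels), IMFs with central frequency below 20 Hz are
excluded, and three metrics are collected into a long-format table —
per-channel IMF counts, one mode-alignment scalar, and one mode-mixing
value (per-channel scores averaged over channels).

Statistics follow the usual repeated-measures workflow: a two-way ANOVA
(program x method) on each metric, a one-way repeated-measures ANOVA on the
per-subject program-averaged values with the method x subject interaction as
error term, and unadjusted LSD pairwise comparisons using that same error
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import InvalidInputError, UndefinedMetricError
from .memd import (
    MultichannelRecording,
    MvStopParams,
    NoiseAssistParams,
    memd,
    na_memd,
)
from .metrics import (
    PsdParams,
    band_summary,
    channel_mode_mixing,
    estimate_psd,
    filter_low_frequency_imfs,
    mode_alignment,
    normalize_imf,
)
from .sift import EnsembleParams, SiftParams, eemd

__all__ = [
    "StudyParams",
    "METHODS",
    "load_mode_alignment_table",
    "load_mode_mixing_table",
    "decompose_recording",
    "evaluate_decomposition",
    "run_comparison",
    "subject_method_means",
    "two_way_anova",
    "rm_anova_oneway",
    "lsd_posthoc",
    "report",
]

METHODS = ("EEMD", "MEMD", "NA-MEMD")


@dataclass(frozen=True)
class StudyParams:
    """All knobs of the comparison pipeline in one place."""

    sift: SiftParams = field(default_factory=SiftParams)
    ensemble: EnsembleParams = field(default_factory=EnsembleParams)
    stop: MvStopParams = field(default_factory=MvStopParams)
    noise_assist: NoiseAssistParams = field(default_factory=NoiseAssistParams)
    n_directions: int = 64
    low_freq_cutoff: float = 20.0
    psd: PsdParams = field(default_factory=PsdParams)
    mixing_rule: Literal["mean", "sum"] = "mean"


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("memdkit").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_mode_alignment_table() -> pd.DataFrame:
    """Per-subject mode-alignment scores from a published lower-limb EMG study.

    11 healthy subjects x 3 exercise programs (sitting, standing, walking) x
    3 methods (EEMD, MEMD, NA-MEMD), values rounded to two decimals as
    printed.  Used for re-analysis of the reported ANOVA statistics.
    """
    return _load_packaged("mode_alignment_by_subject.csv")


def load_mode_mixing_table() -> pd.DataFrame:
    """Per-subject mode-mixing scores companion to the alignment table."""
    return _load_packaged("mode_mixing_by_subject.csv")


def decompose_recording(
    recording: MultichannelRecording, method: str, params: StudyParams | None = None
) -> list[np.ndarray]:
    """Decompose one recording with one method.

    Returns one (M_j, T) IMF stack per channel.  EEMD runs channel by
    channel (counts may differ); MEMD and NA-MEMD decompose all channels
    jointly, so every stack has the same depth.
    """
    params = params or StudyParams()
    if method == "EEMD":
        return [
            eemd(recording.samples[:, j], params.sift, params.ensemble).imfs
            for j in range(recording.n_channels)
        ]
    if method == "MEMD":
        d = memd(recording, params.n_directions, params.stop, params.sift)
    elif method == "NA-MEMD":
        d = na_memd(recording, params.noise_assist, params.n_directions, params.stop, params.sift)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return [d.channel_imfs(j) for j in range(recording.n_channels)]


def evaluate_decomposition(
    per_channel_imfs: Sequence[np.ndarray],
    sampling_rate: float,
    params: StudyParams | None = None,
) -> dict:
    """Apply the 20 Hz rule and compute counts, alignment, and mixing.

    The mode-alignment scalar uses the IMF indices retained (central
    frequency >= cutoff) in *every* channel, so same-index comparison stays
    meaningful; mode-mixing is computed per channel on that channel's own
    retained IMFs and averaged over channels.
    """
    params = params or StudyParams()
    counts = [stack.shape[0] for stack in per_channel_imfs]
    retained_per_channel = []
    for stack in per_channel_imfs:
        retained, _ = filter_low_frequency_imfs(
            stack, sampling_rate, params.low_freq_cutoff, params.psd
        )
        retained_per_channel.append(retained)
    common = sorted(set.intersection(*(set(r) for r in retained_per_channel)))
    alignment = np.nan
    if len(common) >= 1:
        stacks = [stack[common] for stack in per_channel_imfs]
        alignment = mode_alignment(stacks, sampling_rate, params.psd).scalar_summary
    mixing_per_channel = []
    for stack, retained in zip(per_channel_imfs, retained_per_channel):
        if len(retained) < 2:
            continue
        bands = [
            band_summary(estimate_psd(normalize_imf(stack[i]), sampling_rate, params.psd))
            for i in retained
        ]
        mixing_per_channel.append(channel_mode_mixing(bands, params.mixing_rule).aggregate)
    if not mixing_per_channel:
        raise UndefinedMetricError("no channel retained 2 IMFs above the cutoff")
    return {
        "counts": counts,
        "alignment": float(alignment),
        "mixing": float(np.mean(mixing_per_channel)),
    }


def run_comparison(
    recordings: Mapping[tuple[str | int, str], MultichannelRecording],
    methods: Sequence[str] = METHODS,
    params: StudyParams | None = None,
) -> pd.DataFrame:
    """Decompose and score every (subject, program) recording with every method.

    Parameters
    ----------
    recordings : mapping ``(subject, program) -> MultichannelRecording``
    methods : subset of ``("EEMD", "MEMD", "NA-MEMD")``

    Returns a long-format StudyTable with columns
    ``subject, program, method, channel, metric, value`` (``channel`` empty
    for the scalar alignment/mixing metrics).
    """
    params = params or StudyParams()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise InvalidInputError(f"unknown methods: {sorted(unknown)}")
    rows = []
    for (subject, program), rec in recordings.items():
        for method in methods:
            stacks = decompose_recording(rec, method, params)
            scores = evaluate_decomposition(stacks, rec.sampling_rate, params)
            for j, count in enumerate(scores["counts"]):
                rows.append(
                    dict(
                        subject=subject,
                        program=program,
                        method=method,
                        channel=rec.channel_names[j],
                        metric="imf_count",
                        value=float(count),
                    )
                )
            for metric in ("alignment", "mixing"):
                rows.append(
                    dict(
                        subject=subject,
                        program=program,
                        method=method,
                        channel="",
                        metric=metric,
                        value=scores[metric],
                    )
                )
    return pd.DataFrame(rows)


def subject_method_means(table: pd.DataFrame, metric: str | None = None) -> pd.DataFrame:
    """Average a metric over programs, giving a subject x method matrix."""
    df = table
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    if df.empty:
        raise InvalidInputError("no rows for the requested metric")
    pivot = df.pivot_table(index="subject", columns="method", values="value", aggfunc="mean")
    if pivot.isna().any().any():
        missing = [(s, m) for (s, m) in zip(*np.where(pivot.isna().values))]
        raise InvalidInputError(f"missing cells in the design: {missing}")
    return pivot


def _anova_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["source", "ss", "df", "ms", "F", "p"])
    return df


def two_way_anova(table: pd.DataFrame, metric: str | None = None) -> pd.DataFrame:
    """Classical two-way between-cell ANOVA (program x method).

    Subjects act as replicates within each program x method cell; the design
    must be balanced.  Returns a frame with sum of squares, df, mean square,
    F and p per effect (main effects, interaction, error).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    df = df[["program", "method", "value"]].dropna()
    sizes = df.groupby(["program", "method"]).size()
    if sizes.nunique() != 1:
        raise InvalidInputError("design is unbalanced")
    if sizes.iloc[0] < 2:
        raise InvalidInputError(
            "need at least 2 replicates per program x method cell for the interaction model"
        )
    model = ols("value ~ C(program) * C(method)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    labels = {
        "C(program)": "program",
        "C(method)": "method",
        "C(program):C(method)": "program x method",
        "Residual": "error",
    }
    rows = []
    for name, row in aov.iterrows():
        ss, dof = float(row["sum_sq"]), int(row["df"])
        rows.append(
            dict(
                source=labels.get(name, name),
                ss=ss,
                df=dof,
                ms=ss / dof,
                F=float(row["F"]) if np.isfinite(row["F"]) else np.nan,
                p=float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else np.nan,
            )
        )
    return _anova_frame(rows)


def rm_anova_oneway(matrix: pd.DataFrame) -> pd.DataFrame:
    """One-way repeated-measures ANOVA on a subject x condition matrix.

    The condition effect is tested against the subject x condition
    interaction (sphericity assumed): with n subjects and k conditions,
    F = MS_cond / MS_error on (k-1, (n-1)(k-1)) degrees of freedom.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InvalidInputError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("matrix contains missing values")
    n, k = X.shape
    grand = X.mean()
    ss_cond = n * float(((X.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((X.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_subj = k - 1, n - 1
    df_err = df_cond * df_subj
    ms_cond, ms_err = ss_cond / df_cond, ss_err / df_err
    F = ms_cond / ms_err if ms_err > 0 else 0.0
    p = float(sps.f.sf(F, df_cond, df_err)) if ms_err > 0 else 1.0
    return _anova_frame(
        [
            dict(source="condition", ss=ss_cond, df=df_cond, ms=ms_cond, F=F, p=p),
            dict(
                source="subject",
                ss=ss_subj,
                df=df_subj,
                ms=ss_subj / df_subj,
                F=np.nan,
                p=np.nan,
            ),
            dict(source="error", ss=ss_err, df=df_err, ms=ms_err, F=np.nan, p=np.nan),
        ]
    )


def lsd_posthoc(matrix: pd.DataFrame) -> pd.DataFrame:
    """Least-significant-difference pairwise comparisons after RM ANOVA.

    Each pair of conditions is compared with an unadjusted t statistic
    ``(mean_a - mean_b) / sqrt(2 MS_err / n)`` on the repeated-measures
    error degrees of freedom.
    """
    aov = rm_anova_oneway(matrix)
    ms_err = float(aov.loc[aov["source"] == "error", "ms"].iloc[0])
    df_err = int(aov.loc[aov["source"] == "error", "df"].iloc[0])
    n = matrix.shape[0]
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else [
        f"cond{i}" for i in range(np.asarray(matrix).shape[1])
    ]
    means = np.asarray(matrix, dtype=np.float64).mean(axis=0)
    se = np.sqrt(2 * ms_err / n)
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            diff = means[a] - means[b]
            t = diff / se if se > 0 else 0.0
            p = float(2 * sps.t.sf(abs(t), df_err)) if se > 0 else 1.0
            rows.append(
                dict(pair=f"{names[a]} vs {names[b]}", difference=diff, t=t, df=df_err, p=p)
            )
    return pd.DataFrame(rows)


def report(
    table: pd.DataFrame,
    outdir,
    metrics: Sequence[str] = ("alignment", "mixing"),
    make_plots: bool = False,
) -> dict:
    """Write the study outputs (tables, ANOVA summaries, JSON) to ``outdir``.

    Produces, with deterministic names: ``study_table.csv``, per-metric
    ``anova_twoway_<metric>.csv``, ``anova_rm_<metric>.csv``,
    ``lsd_<metric>.csv``, an IMF count table, and ``summary.json``.
    """
    import json
    from pathlib import Path

    if table.empty:
        raise InvalidInputError("empty study table; nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    table = table.sort_values(["metric", "subject", "program", "method", "channel"]).reset_index(
        drop=True
    )
    p = outdir / "study_table.csv"
    table.to_csv(p, index=False)
    paths["study_table"] = str(p)

    counts = table[table["metric"] == "imf_count"]
    if not counts.empty:
        pivot = counts.pivot_table(
            index="method", columns="channel", values="value", aggfunc=["mean", "std"]
        )
        p = outdir / "imf_count_table.csv"
        pivot.to_csv(p)
        paths["imf_count_table"] = str(p)

    summary: dict = {"methods": {}, "anova": {}}
    for metric in metrics:
        sub = table[table["metric"] == metric]
        if sub.empty:
            continue
        summary["methods"][metric] = (
            sub.groupby("method")["value"].mean().round(6).to_dict()
        )
        if sub["program"].nunique() >= 2 and sub["method"].nunique() >= 2:
            try:
                aov2 = two_way_anova(sub)
            except InvalidInputError:
                aov2 = None  # saturated or unbalanced design; skip this table
            if aov2 is not None:
                p = outdir / f"anova_twoway_{metric}.csv"
                aov2.to_csv(p, index=False)
                paths[f"anova_twoway_{metric}"] = str(p)
        means = subject_method_means(sub)
        if means.shape[0] >= 2 and means.shape[1] >= 2:
            aov_rm = rm_anova_oneway(means)
            p = outdir / f"anova_rm_{metric}.csv"
            aov_rm.to_csv(p, index=False)
            paths[f"anova_rm_{metric}"] = str(p)
            lsd = lsd_posthoc(means)
            p = outdir / f"lsd_{metric}.csv"
            lsd.to_csv(p, index=False)
            paths[f"lsd_{metric}"] = str(p)
            cond = aov_rm.iloc[0]
            summary["anova"][metric] = {
                "F": round(float(cond["F"]), 6),
                "p": float(cond["p"]),
            }
    p = outdir / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    paths["summary"] = str(p)
    if make_plots:
        paths.update(_plot_method_means(table, outdir, metrics))
    return paths


def _plot_method_means(table: pd.DataFrame, outdir, metrics) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    for metric in metrics:
        sub = table[table["metric"] == metric]
        if sub.empty:
            continue
        stats = sub.groupby("method")["value"].agg(["mean", "std"])
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(stats.index, stats["mean"], yerr=stats["std"].fillna(0), capsize=4)
        ax.set_ylabel(metric)
        fig.tight_layout()
        p = outdir / f"method_means_{metric}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"plot_{metric}"] = str(p)
    return paths
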