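"""Pupariation-timing statistics and hit classification for a high-sugar-diet screen.

The screen readout is the cumulative fraction of larvae in a vial that have
pupariated at each observation time.  The central statistic is P50 -- the time
at which half the larvae have pupariated, obtained by linear interpolation
between the observations flanking the 50% point.  A gene's *excess delay* is
the high-sugar-minus-normal-diet shift of its P50 relative to the same shift
in driver-only controls, and hit classes distinguish sugar-dependent (SD)
phenotypes (arrest or delay only on high sugar) from partially sugar-dependent
(PSD) phenotypes (present on both diets, stronger on high sugar).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PupariationCurve",
    "P50Result",
    "DelayStat",
    "HitCall",
    "HitThresholds",
    "GenotypeStats",
    "InsufficientReplicatesError",
    "HIT_CLASSES",
    "p50_time",
    "excess_delay",
    "genotype_stats",
    "classify_hit",
    "screen_summary",
    "interaction_test",
    "crowding_check",
    "curves_from_table",
]

#: Hit classes: SD_* = phenotype only on high sugar; PSD_* = phenotype on both
#: diets, stronger on high sugar.
HIT_CLASSES = (
    "none",
    "SD_full_arrest",
    "SD_partial_arrest",
    "SD_delay",
    "PSD_delay_then_full_arrest",
    "PSD_delay_then_partial_arrest",
    "PSD_partial_then_full_arrest",
)

#: Minimum pupae for a vial's P50 to enter replicate averaging.
MIN_PUPAE_FOR_P50 = 3


class InsufficientReplicatesError(ValueError):
    """No qualifying replicate (>= 3 pupae, 50% reached) in a genotype x diet cell.

    Distinct from developmental arrest: arrest is a biological outcome carried
    by :class:`P50Result`; this error means the statistic cannot be formed.
    """


@dataclass(frozen=True)
class PupariationCurve:
    """Cumulative pupariation fraction versus time for one genotype x diet x vial.

    Times are continuous hours after the midpoint of the egg-laying window.
    """

    genotype: str
    diet: str
    vial: str
    obs_times: tuple[float, ...]
    cum_fraction: tuple[float, ...]
    n_pupae_final: int
    n_seeded: int

    def __post_init__(self) -> None:
        t = np.asarray(self.obs_times, dtype=float)
        f = np.asarray(self.cum_fraction, dtype=float)
        if t.size == 0:
            raise ValueError("empty curve")
        if t.size != f.size:
            raise ValueError("obs_times and cum_fraction differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("obs_times must be strictly increasing")
        if np.any(np.diff(f) < 0):
            raise ValueError("cum_fraction must be non-decreasing")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("cum_fraction must lie in [0, 1]")

    @classmethod
    def from_counts(
        cls,
        genotype: str,
        diet: str,
        vial: str,
        obs_times: Sequence[float],
        cum_pupae: Sequence[int],
        n_seeded: int,
    ) -> "PupariationCurve":
        pupae = np.asarray(cum_pupae, dtype=float)
        if n_seeded < 1:
            raise ValueError("n_seeded must be >= 1")
        if np.any(pupae > n_seeded):
            raise ValueError("cumulative pupae exceed larvae seeded")
        return cls(
            genotype=genotype,
            diet=diet,
            vial=str(vial),
            obs_times=tuple(float(t) for t in obs_times),
            cum_fraction=tuple(pupae / n_seeded),
            n_pupae_final=int(pupae[-1]),
            n_seeded=int(n_seeded),
        )


@dataclass(frozen=True)
class P50Result:
    """Time to 50% pupariation for one vial.

    ``reached`` is False when the curve plateaus below 50% (developmental
    arrest); ``p50`` is then NaN.  ``qualifies`` marks vials with at least
    three pupae, the replicate-inclusion rule used when averaging P50s.
    """

    p50: float
    reached: bool
    n_pupae_final: int
    qualifies: bool

    @property
    def arrested(self) -> bool:
        return not self.reached


@dataclass(frozen=True)
class DelayStat:
    """Excess high-sugar delay of a genotype relative to controls.

    excess_delay = (P50_g,HSD - P50_g,ND) - (P50_c,HSD - P50_c,ND), in hours,
    computed on replicate-mean P50s; ``se`` propagates the four cell SEMs.
    """

    genotype: str
    delay_nd: float
    delay_hsd: float
    excess_delay: float
    se: float


@dataclass(frozen=True)
class GenotypeStats:
    """Per-genotype screen statistics: one entry per diet."""

    genotype: str
    frac: Mapping[str, float]          # final pupariation fraction by diet
    p50_mean: Mapping[str, float]      # NaN when 50% never reached
    p50_reps: Mapping[str, tuple[float, ...]]  # qualifying replicate P50s


@dataclass(frozen=True)
class HitThresholds:
    """Decision thresholds for hit classification.

    delay_h: minimum excess delay (hours) to call a delay phenotype; half a
    day separates biological delay from scoring granularity at daily cadence.
    partial_arrest_max: pupariation fraction below this (and above zero) is a
    partial arrest; full arrest is a fraction of exactly zero.
    alpha: significance level for the replicate-level interaction test, only
    applied when replicate P50s are available.
    """

    delay_h: float = 12.0
    partial_arrest_max: float = 0.5
    alpha: float = 0.05
    require_significance: bool = True


@dataclass(frozen=True)
class HitCall:
    genotype: str
    hit_class: str
    delay: DelayStat | None
    frac_nd: float
    frac_hsd: float
    p_interaction: float | None = None


def p50_time(curve: PupariationCurve) -> P50Result:
    """Time of 50% pupariation by linear interpolation between flanking observations.

    If an observation sits exactly at 50%, that time is returned (the earliest
    such time if a plateau spans several observations).  If the curve never
    reaches 50%, the vial is arrested and ``p50`` is NaN.
    """
    t = np.asarray(curve.obs_times, dtype=float)
    f = np.asarray(curve.cum_fraction, dtype=float)
    qualifies = curve.n_pupae_final >= MIN_PUPAE_FOR_P50
    if f.max() < 0.5:
        return P50Result(math.nan, False, curve.n_pupae_final, qualifies)
    exact = np.nonzero(f == 0.5)[0]
    if exact.size:
        p50 = float(t[exact[0]])
    else:
        j = int(np.argmax(f >= 0.5))  # first index at/above 0.5
        if j == 0:
            # already above 50% at the first observation; no flanking pair
            p50 = float(t[0])
        else:
            i = j - 1
            p50 = float(t[i] + (0.5 - f[i]) / (f[j] - f[i]) * (t[j] - t[i]))
    return P50Result(p50, True, curve.n_pupae_final, qualifies)


def _cell_p50s(curves: Iterable[PupariationCurve]) -> list[float]:
    """Qualifying replicate P50s (>= 3 pupae and 50% reached) of one cell."""
    out = []
    for c in curves:
        r = p50_time(c)
        if r.qualifies and r.reached:
            out.append(r.p50)
    return out


def excess_delay(
    genotype_curves: Mapping[str, Sequence[PupariationCurve]],
    control_curves: Mapping[str, Sequence[PupariationCurve]],
    nd: str = "ND",
    hsd: str = "HSD",
) -> DelayStat:
    """Excess high-sugar-diet delay of a genotype relative to controls.

    Both arguments map diet label -> replicate curves.  Replicates with fewer
    than three pupae, or that never reach 50%, are excluded before averaging;
    a cell with no qualifying replicate raises
    :class:`InsufficientReplicatesError`.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for tag, curves in (("genotype", genotype_curves), ("control", control_curves)):
        for diet in (nd, hsd):
            reps = _cell_p50s(curves.get(diet, ()))
            if not reps:
                raise InsufficientReplicatesError(
                    f"no qualifying replicates for {tag} on diet {diet!r}"
                )
            cells[(tag, diet)] = reps

    def mean_sem(v: list[float]) -> tuple[float, float]:
        a = np.asarray(v, dtype=float)
        sem = float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0
        return float(a.mean()), sem

    (g_nd, se_gn) = mean_sem(cells[("genotype", nd)])
    (g_hs, se_gh) = mean_sem(cells[("genotype", hsd)])
    (c_nd, se_cn) = mean_sem(cells[("control", nd)])
    (c_hs, se_ch) = mean_sem(cells[("control", hsd)])

    genotype = next(iter(genotype_curves.values()))[0].genotype
    return DelayStat(
        genotype=genotype,
        delay_nd=g_nd - c_nd,
        delay_hsd=g_hs - c_hs,
        excess_delay=(g_hs - g_nd) - (c_hs - c_nd),
        se=math.sqrt(se_gn**2 + se_gh**2 + se_cn**2 + se_ch**2),
    )


def genotype_stats(
    curves_by_diet: Mapping[str, Sequence[PupariationCurve]],
) -> GenotypeStats:
    """Pool replicate curves of one genotype into per-diet screen statistics.

    The final pupariation fraction pools pupae and seeded larvae across all
    vials (vials with zero pupae still count toward arrest evidence); the P50
    mean averages qualifying replicates only.
    """
    frac: dict[str, float] = {}
    p50_mean: dict[str, float] = {}
    p50_reps: dict[str, tuple[float, ...]] = {}
    genotype = ""
    for diet, curves in curves_by_diet.items():
        if not curves:
            raise ValueError(f"no curves for diet {diet!r}")
        genotype = curves[0].genotype
        pupae = sum(c.n_pupae_final for c in curves)
        seeded = sum(c.n_seeded for c in curves)
        frac[diet] = pupae / seeded
        reps = _cell_p50s(curves)
        p50_reps[diet] = tuple(reps)
        p50_mean[diet] = float(np.mean(reps)) if reps else math.nan
    return GenotypeStats(genotype=genotype, frac=frac, p50_mean=p50_mean, p50_reps=p50_reps)


def _severity(frac: float, delayed: bool, partial_max: float) -> str:
    if frac == 0.0:
        return "full"
    if frac < partial_max:
        return "partial"
    return "delay" if delayed else "none"


def classify_hit(
    genotype: GenotypeStats,
    control: GenotypeStats,
    thresholds: HitThresholds | None = None,
    nd: str = "ND",
    hsd: str = "HSD",
) -> HitCall:
    """Assign a screen hit class from per-diet pupariation statistics.

    The decision tree crosses the normal-diet phenotype (none / delay /
    partial arrest / full arrest) with the high-sugar-diet severity.  A delay
    phenotype requires the delay statistic to exceed ``thresholds.delay_h``
    and, when replicate P50s are available in all four cells and
    ``require_significance`` is set, a genotype x diet interaction p-value
    below ``thresholds.alpha``.  Genotypes with no high-sugar phenotype, and
    diet-independent combinations outside the taxonomy, are "none".
    """
    th = thresholds or HitThresholds()
    if control is None:
        raise ValueError("missing control reference")

    # Delay statistics relative to control on each diet (NaN when undefined).
    d_nd = genotype.p50_mean.get(nd, math.nan) - control.p50_mean.get(nd, math.nan)
    d_hsd = genotype.p50_mean.get(hsd, math.nan) - control.p50_mean.get(hsd, math.nan)
    exc = d_hsd - d_nd

    p_int: float | None = None
    sig = True
    have_reps = all(
        len(s.p50_reps.get(d, ())) >= 2 for s in (genotype, control) for d in (nd, hsd)
    )
    if th.require_significance and have_reps:
        rows = []
        for s, label in ((genotype, "g"), (control, "c")):
            for d in (nd, hsd):
                rows += [{"genotype": label, "diet": d, "p50": v} for v in s.p50_reps[d]]
        p_int = interaction_test(pd.DataFrame(rows))
        sig = p_int < th.alpha

    delayed_nd = math.isfinite(d_nd) and d_nd >= th.delay_h
    delayed_hsd = math.isfinite(exc) and exc >= th.delay_h and sig

    nd_sev = _severity(genotype.frac.get(nd, math.nan), delayed_nd, th.partial_arrest_max)
    hsd_sev = _severity(genotype.frac.get(hsd, math.nan), delayed_hsd, th.partial_arrest_max)

    table = {
        ("none", "full"): "SD_full_arrest",
        ("none", "partial"): "SD_partial_arrest",
        ("none", "delay"): "SD_delay",
        ("delay", "full"): "PSD_delay_then_full_arrest",
        ("delay", "partial"): "PSD_delay_then_partial_arrest",
        ("partial", "full"): "PSD_partial_then_full_arrest",
    }
    hit_class = table.get((nd_sev, hsd_sev), "none")

    delay_stat = None
    if math.isfinite(exc):
        delay_stat = DelayStat(genotype.genotype, d_nd, d_hsd, exc, math.nan)
    return HitCall(
        genotype=genotype.genotype,
        hit_class=hit_class,
        delay=delay_stat,
        frac_nd=genotype.frac.get(nd, math.nan),
        frac_hsd=genotype.frac.get(hsd, math.nan),
        p_interaction=p_int,
    )


def screen_summary(
    hits: Sequence[HitCall] | pd.DataFrame,
    n_genes_screened: int,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Summarise a screen: hit rate, class counts, and annotation breakdowns.

    ``annotations`` is keyed by gene with boolean columns
    ``has_human_ortholog``, ``disease_associated``,
    ``obesity_diabetes_associated``.  Hit genes missing from the annotation
    table are counted as unannotated (with a warning).  The partially
    sugar-dependent class size is n_hits - n_sugar_dependent_only.
    """
    if isinstance(hits, pd.DataFrame):
        records = hits[["genotype", "hit_class"]].to_dict("records")
    else:
        records = [{"genotype": h.genotype, "hit_class": h.hit_class} for h in hits]

    hit_records = [r for r in records if r["hit_class"] != "none"]
    n_hits = len(hit_records)
    class_counts = {c: 0 for c in HIT_CLASSES if c != "none"}
    for r in hit_records:
        class_counts[r["hit_class"]] += 1
    n_sd_only = sum(v for c, v in class_counts.items() if c.startswith("SD_"))
    n_psd = n_hits - n_sd_only
    hit_rate = round(100.0 * n_hits / n_genes_screened, 1) if n_genes_screened else 0.0

    summary = {
        "n_genes_screened": int(n_genes_screened),
        "n_hits": n_hits,
        "hit_rate_pct": hit_rate,
        "class_counts": class_counts,
        "n_sugar_dependent_only": n_sd_only,
        "n_partially_sugar_dependent": n_psd,
    }

    if annotations is not None:
        ann = annotations.set_index(annotations.columns[0]) if annotations.index.name is None else annotations
        cols = ("has_human_ortholog", "disease_associated", "obesity_diabetes_associated")
        groups = {
            "sugar_dependent": [r["genotype"] for r in hit_records if r["hit_class"].startswith("SD_")],
            "partially_sugar_dependent": [r["genotype"] for r in hit_records if r["hit_class"].startswith("PSD_")],
        }
        missing = [g for gs in groups.values() for g in gs if g not in ann.index]
        if missing:
            warnings.warn(
                f"{len(missing)} hit gene(s) missing from annotation table; counted as unannotated",
                stacklevel=2,
            )
        breakdown: dict[str, dict] = {}
        for name, genes in groups.items():
            present = [g for g in genes if g in ann.index]
            entry: dict[str, float | int] = {"n": len(genes)}
            for col in cols:
                if col in ann.columns:
                    k = int(ann.loc[present, col].astype(bool).sum()) if present else 0
                    entry[f"n_{col}"] = k
                    entry[f"pct_{col}"] = round(100.0 * k / len(genes)) if genes else 0
            breakdown[name] = entry
        summary["annotation"] = breakdown

    return summary


def interaction_test(p50_table: pd.DataFrame) -> float:
    """p-value of the genotype x diet interaction in a two-way ANOVA with replication.

    ``p50_table`` needs columns genotype, diet, p50 with >= 2 replicates in
    each of the 2 x 2 cells.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    counts = p50_table.groupby(["genotype", "diet"], observed=True).size()
    if (counts < 2).any() or len(counts) < 4:
        raise ValueError("interaction test needs >= 2 replicates in every genotype x diet cell")
    model = ols("p50 ~ C(genotype) * C(diet)", data=p50_table).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    p = float(tab.loc["C(genotype):C(diet)", "PR(>F)"])
    return 1.0 if math.isnan(p) else p


def crowding_check(
    p50_table: pd.DataFrame,
    density_col: str = "density",
    diet_col: str = "diet",
    value_col: str = "p50",
) -> dict:
    """One-way ANOVA of P50 across larval-density groups, per diet.

    Verifies the design assumption that vial crowding (5-150 larvae) does not
    shift pupariation timing.  Returns per-diet p-values and density means.
    """
    out: dict[str, dict] = {}
    for diet, sub in p50_table.groupby(diet_col, observed=True):
        groups = [g[value_col].to_numpy(float) for _, g in sub.groupby(density_col, observed=True)]
        if len(groups) < 2:
            raise ValueError("crowding check needs >= 2 density groups")
        f, p = sps.f_oneway(*groups)
        means = sub.groupby(density_col, observed=True)[value_col].mean().to_dict()
        out[str(diet)] = {"p": float(p), "F": float(f), "means": {str(k): float(v) for k, v in means.items()}}
    return out


def curves_from_table(events: pd.DataFrame) -> list[PupariationCurve]:
    """Build curves from a long-format event table.

    Expected columns: genotype, diet, vial, obs_time_h, cum_pupae, n_seeded
    (an optional gene column is folded into genotype when present).
    """
    df = events.copy()
    if "genotype" not in df.columns and "gene" in df.columns:
        df = df.rename(columns={"gene": "genotype"})
    curves = []
    for (gt, diet, vial), grp in df.groupby(["genotype", "diet", "vial"], observed=True, sort=True):
        grp = grp.sort_values("obs_time_h")
        n_seeded = int(grp["n_seeded"].iloc[0])
        curves.append(
            PupariationCurve.from_counts(
                genotype=str(gt),
                diet=str(diet),
                vial=str(vial),
                obs_times=grp["obs_time_h"].to_list(),
                cum_pupae=grp["cum_pupae"].to_list(),
                n_seeded=n_seeded,
            )
        )
    return curves
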