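"""Insulin-response phosphoproteomics analysis.

Works on a phosphosite quantification table (one abundance column per
labelling channel) plus a design table mapping channels to (genotype,
treatment, replicate).  The analysis chain: equalise channel totals, compute
per-site insulin/mock fold changes within a genotype, call responses at the
>30% threshold (in either direction), count them, derive the set of
control-responsive sites whose response is lost in receptor-knockdown
genotypes, collapse sites to proteins, and test protein sets for pathway
overrepresentation with a two-sided Fisher exact test.

The 30% down-regulation cut is applied on the reciprocal scale by default
(fold change <= 1/1.3, symmetric with the 1.3x up cut on the log scale); a
plain-ratio mode (<= 0.7) is available since either reading of "a > 30%
difference in either direction" is defensible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ResponseSet",
    "normalize_channels",
    "site_anova",
    "insulin_response",
    "count_changes",
    "dependent_set",
    "dedupe_proteins",
    "venn_overlap",
    "enrichment",
    "DependenceResult",
]

#: default response threshold: fold change beyond 1 + theta (or its reciprocal)
DEFAULT_THETA = 0.30


@dataclass(frozen=True)
class ResponseSet:
    """Counted insulin-response changes for one genotype."""

    genotype: str
    up_sites: frozenset
    down_sites: frozenset

    @property
    def n_up(self) -> int:
        return len(self.up_sites)

    @property
    def n_down(self) -> int:
        return len(self.down_sites)

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


@dataclass(frozen=True)
class DependenceResult:
    """Control-responsive sites that show no response in the knockdowns."""

    sites: frozenset
    n_up: int
    n_down: int
    n_control_total: int

    @property
    def n_total(self) -> int:
        return len(self.sites)

    @property
    def fraction_pct(self) -> int:
        """Dependent share of the control response, as an integer percent."""
        if self.n_control_total == 0:
            return 0
        return round(100.0 * self.n_total / self.n_control_total)


def _channel_cols(table: pd.DataFrame, design: pd.DataFrame) -> list[str]:
    cols = [c for c in design["channel"] if c in table.columns]
    missing = set(design["channel"]) - set(cols)
    if missing:
        raise ValueError(f"design channels missing from table: {sorted(missing)}")
    return cols


def normalize_channels(table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel so all channel totals equal the grand mean total.

    Mirrors total-signal normalization of isobaric reporter intensities;
    within-channel ratios are preserved exactly and the operation is
    idempotent.
    """
    cols = _channel_cols(table, design)
    out = table.copy()
    totals = out[cols].sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total channel(s): {bad}")
    if (out[cols].to_numpy() <= 0).any():
        raise ValueError("abundances must be positive")
    target = totals.mean()
    out[cols] = out[cols] / totals * target
    return out


def site_anova(
    table: pd.DataFrame,
    design: pd.DataFrame,
    group_cols: Sequence[str] = ("genotype", "treatment"),
) -> pd.Series:
    """One-way ANOVA p-value per phosphosite across condition groups.

    Abundances are log2-transformed first.  Degenerate sites with zero
    between- and within-group variance get p = 1 by convention; zero
    within-group variance with distinct means gives p = 0.
    """
    cols = _channel_cols(table, design)
    key = design.set_index("channel").loc[cols, list(group_cols)].astype(str).agg("|".join, axis=1)
    groups = [np.asarray(g.index) for _, g in key.groupby(key)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("site_anova needs >= 2 groups with >= 2 replicates each")

    X = np.log2(table[cols].to_numpy(dtype=float))
    k = len(groups)
    n = X.shape[1]
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g in groups:
        idx = [cols.index(c) for c in g]
        sub = X[:, idx]
        gm = sub.mean(axis=1)
        ssb += len(idx) * (gm - grand) ** 2
        ssw += ((sub - gm[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
        p = sps.f.sf(F, df_b, df_w)
    p = np.where(ssw == 0, np.where(ssb == 0, 1.0, 0.0), p)
    return pd.Series(p, index=table["site_id"].to_numpy(), name="p")


def insulin_response(
    table: pd.DataFrame,
    design: pd.DataFrame,
    genotype: str,
    theta: float = DEFAULT_THETA,
    down_rule: str = "reciprocal",
    normalized: bool = False,
    with_p: bool = True,
) -> pd.DataFrame:
    """Per-site insulin/mock fold changes and response directions for one genotype.

    The fold change is the ratio of replicate-mean normalized abundances,
    insulin over mock.  Direction is "up" when fold_change >= 1 + theta,
    "down" when fold_change <= 1/(1 + theta) (``down_rule="reciprocal"``, the
    default) or <= 1 - theta (``down_rule="linear"``), else "none".  A
    two-sample t-test on log2 abundances supplies the per-site p-value used
    in volcano outputs (the counting filter itself is fold-change-only).
    """
    if down_rule not in ("reciprocal", "linear"):
        raise ValueError("down_rule must be 'reciprocal' or 'linear'")
    sub = design[design["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"genotype {genotype!r} not in design")
    ins = sub.loc[sub["treatment"] == "insulin", "channel"].tolist()
    mock = sub.loc[sub["treatment"] == "mock", "channel"].tolist()
    if not ins or not mock:
        raise ValueError(f"genotype {genotype!r} is missing a treatment arm")

    t = table if normalized else normalize_channels(table, design)
    ins_mean = t[ins].mean(axis=1)
    mock_mean = t[mock].mean(axis=1)
    fc = (ins_mean / mock_mean).to_numpy(dtype=float)

    down_cut = 1.0 / (1.0 + theta) if down_rule == "reciprocal" else 1.0 - theta
    direction = np.where(fc >= 1.0 + theta, "up", np.where(fc <= down_cut, "down", "none"))

    out = pd.DataFrame(
        {
            "site_id": t["site_id"].to_numpy(),
            "protein_id": t["protein_id"].to_numpy(),
            "fold_change": fc,
            "direction": direction,
        }
    )
    if with_p:
        a = np.log2(t[ins].to_numpy(dtype=float))
        b = np.log2(t[mock].to_numpy(dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # noiseless synthetic data makes the t-test degenerate; p becomes 1
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = sps.ttest_ind(a, b, axis=1)
        out["p"] = np.where(np.isnan(p), 1.0, p)
    return out


def count_changes(responses: pd.DataFrame, genotype: str = "") -> ResponseSet:
    """Count up/down insulin-response changes from one genotype's response table."""
    if len(responses):
        up = frozenset(responses.loc[responses["direction"] == "up", "site_id"])
        down = frozenset(responses.loc[responses["direction"] == "down", "site_id"])
    else:
        up = down = frozenset()
    return ResponseSet(genotype=genotype, up_sites=up, down_sites=down)


def dependent_set(
    control_responses: pd.DataFrame,
    kd_responses: Sequence[pd.DataFrame],
    mode: str = "all",
) -> DependenceResult:
    """Control-regulated sites whose direction is "none" in the knockdowns.

    ``mode="all"`` (default) requires no response in every knockdown;
    ``mode="any"`` requires it in at least one.  All inputs must share the
    same site universe.  The result keeps the control's up/down split and the
    dependent fraction of the total control response (integer percent).
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    universe = set(control_responses["site_id"])
    for kd in kd_responses:
        if set(kd["site_id"]) != universe:
            raise ValueError("site universes differ between genotypes")

    ctrl = control_responses.set_index("site_id")
    regulated = ctrl.index[ctrl["direction"] != "none"]
    none_masks = []
    for kd in kd_responses:
        d = kd.set_index("site_id").loc[regulated, "direction"]
        none_masks.append(d == "none")
    if none_masks:
        combined = none_masks[0]
        for m in none_masks[1:]:
            combined = (combined & m) if mode == "all" else (combined | m)
    else:
        combined = pd.Series(False, index=regulated)

    dep = set(regulated[combined.to_numpy()])
    ctrl_dir = ctrl.loc[list(dep), "direction"] if dep else pd.Series(dtype=object)
    n_up = int((ctrl_dir == "up").sum())
    n_down = int((ctrl_dir == "down").sum())
    return DependenceResult(
        sites=frozenset(dep),
        n_up=n_up,
        n_down=n_down,
        n_control_total=int((ctrl["direction"] != "none").sum()),
    )


def dedupe_proteins(
    sites: Iterable[str],
    site_to_protein: Mapping[str, str],
) -> set[str]:
    """Unique protein ids of a site set (repeated proteins removed)."""
    out = set()
    for s in sites:
        if s not in site_to_protein:
            raise KeyError(f"site {s!r} has no protein mapping")
        out.add(site_to_protein[s])
    return out


def venn_overlap(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every intersection region of >= 2 named sets.

    Keys are tuples of the set names an element belongs to (exclusively);
    region counts sum to the size of the union.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("venn_overlap needs >= 2 sets")
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            for other in names:
                if other not in members:
                    inside -= sets[other]
            out[members] = len(inside)
    return out


def enrichment(
    hit_proteins: set,
    background_proteins: set,
    pathways: Mapping[str, set],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher exact overrepresentation test per pathway.

    Each pathway set is intersected with the background; pathways disjoint
    from the background are skipped with a warning.  The 2x2 table per
    pathway is (hits-in-pathway, hits-outside, non-hits-in-pathway,
    non-hits-outside); ``significant`` marks raw p < alpha (no multiplicity
    correction, matching per-pathway reporting).
    """
    if not background_proteins:
        raise ValueError("empty background")
    if not hit_proteins <= background_proteins:
        raise ValueError("hit proteins must be a subset of the background")
    rows = []
    n_bg = len(background_proteins)
    n_hit = len(hit_proteins)
    for name, members in pathways.items():
        path = members & background_proteins
        if not path:
            warnings.warn(f"pathway {name!r} has no overlap with background; skipped", stacklevel=2)
            continue
        a = len(hit_proteins & path)
        b = n_hit - a
        c = len(path) - a
        d = n_bg - n_hit - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "pathway": name,
                "n_pathway": len(path),
                "n_hit_in_pathway": a,
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "n_pathway", "n_hit_in_pathway", "p", "significant"])
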