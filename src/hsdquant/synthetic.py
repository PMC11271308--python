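"""Synthetic multi-assay data with planted ground truth.

Every generator here emulates one of the pipeline's input modalities so that
each downstream stage can be tested against known planted parameters:

* vial-level pupariation event tables with diet-dependent delay and arrest;
* fat-body-like image stacks with nuclei, membrane, reporter and droplet
  channels plus truth masks;
* two-channel calcium-imaging frame series with planted transients;
* an 18-channel phosphosite design (3 genotypes x 2 treatments x 3
  replicates) with an insulin response blunted in knockdown genotypes;
* linear Beer-Lambert plate-reader absorbances.

Pupariation event times are drawn from a normal distribution truncated at
zero (the sigmoid shape of cumulative curves motivates this simplest choice),
and arrest is a per-larva Bernoulli censoring event.  All randomness flows
from the integer seed carried in each parameter object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pupariation import HIT_CLASSES

__all__ = [
    "PupSimParams",
    "ImageSimParams",
    "PhosphoSimParams",
    "sim_pupariation",
    "sim_screen",
    "sim_fatbody_image",
    "sim_neuron_frames",
    "sim_phospho",
    "sim_plate",
    "DEFAULT_CLASS_EFFECTS",
]


@dataclass(frozen=True)
class PupSimParams:
    """Pupariation-assay simulation parameters.

    p50_base is the median pupariation time (hours after egg laying) on the
    normal diet; high-sugar vials are shifted by control_diet_effect plus, for
    perturbed genotypes, excess_delay.  arrest_prob censors larvae that never
    pupariate.  Observations land on a regular grid every obs_interval hours;
    follow-up assays score every 8 h, the screen once per day (24 h).
    """

    n_vials: int = 5
    larvae_per_vial: int = 30
    p50_base: float = 110.0
    sd_pup: float = 6.0
    excess_delay: float = 0.0
    control_diet_effect: float = 40.0
    arrest_prob: float = 0.0
    obs_interval: float = 8.0
    obs_end: float = 360.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vials < 1 or self.larvae_per_vial < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.arrest_prob <= 1.0:
            raise ValueError("arrest_prob must lie in [0, 1]")
        if self.sd_pup <= 0:
            raise ValueError("sd_pup must be > 0")
        if self.obs_interval <= 0:
            raise ValueError("obs_interval must be > 0")


@dataclass(frozen=True)
class ImageSimParams:
    """Fat-body image simulation parameters.

    membrane_enrichment is the ratio of membrane to cytoplasm mean reporter
    intensity (>= 1); droplet_area_fraction is the planted fraction of cell
    area covered by lipid droplets.
    """

    shape: tuple[int, int] = (240, 240)
    n_cells: int = 16
    membrane_enrichment: float = 2.0
    droplet_area_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membrane_enrichment < 1.0:
            raise ValueError("membrane_enrichment must be >= 1")
        if not 0.0 <= self.droplet_area_fraction < 1.0:
            raise ValueError("droplet_area_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhosphoSimParams:
    """18-plex phosphoproteomics simulation parameters.

    Three genotypes (control, KD1, KD2) x two treatments (mock, insulin) x
    n_replicates channels.  frac_responsive of the sites carry a planted
    insulin effect of +/- mean_log2_effect log2 units in the control genotype;
    knockdown genotypes see that effect multiplied by ``blunting`` (0 = fully
    blunted).  noise_sd is log2-scale measurement noise.
    """

    n_sites: int = 2000
    n_proteins: int = 600
    frac_responsive: float = 0.2
    mean_log2_effect: float = 1.0
    blunting: float = 0.2
    n_replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_responsive <= 1.0:
            raise ValueError("frac_responsive must lie in [0, 1]")
        if not 0.0 <= self.blunting <= 1.0:
            raise ValueError("blunting must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_sites < 1 or self.n_proteins < 1:
            raise ValueError("counts must be >= 1")


def sim_pupariation(
    params: PupSimParams,
    genotype: str = "control",
    diet: str = "ND",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one genotype x diet pupariation event table.

    High-sugar vials (any diet label other than "ND"/"1x") shift the mean
    pupariation time by control_diet_effect + excess_delay.  Returns a
    long-format table (genotype, diet, vial, obs_time_h, cum_pupae, n_seeded)
    with cumulative counts non-decreasing per vial.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    high_sugar = diet not in ("ND", "1x")
    mean = params.p50_base
    if high_sugar:
        mean += params.control_diet_effect + params.excess_delay
    obs = np.arange(params.obs_interval, params.obs_end + 1e-9, params.obs_interval)

    rows = []
    for v in range(params.n_vials):
        arrested = rng.random(params.larvae_per_vial) < params.arrest_prob
        times = rng.normal(mean, params.sd_pup, params.larvae_per_vial)
        # truncate at zero: redraw non-positive event times
        bad = times <= 0
        while bad.any():
            times[bad] = rng.normal(mean, params.sd_pup, int(bad.sum()))
            bad = times <= 0
        times = times[~arrested]
        cum = (times[None, :] <= obs[:, None]).sum(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "genotype": genotype,
                    "diet": diet,
                    "vial": f"{genotype}_{diet}_v{v + 1}",
                    "obs_time_h": obs,
                    "cum_pupae": cum.astype(int),
                    "n_seeded": params.larvae_per_vial,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


#: Planted effect sizes per hit class, chosen well clear of the default
#: classification thresholds (delay threshold 12 h, partial-arrest cut 0.5).
DEFAULT_CLASS_EFFECTS: dict[str, dict[str, float]] = {
    "none": {},
    "SD_full_arrest": {"hsd_arrest": 1.0},
    "SD_partial_arrest": {"hsd_arrest": 0.7},
    "SD_delay": {"excess_delay": 24.0},
    "PSD_delay_then_full_arrest": {"nd_delay": 24.0, "hsd_arrest": 1.0},
    "PSD_delay_then_partial_arrest": {"nd_delay": 24.0, "hsd_arrest": 0.7},
    "PSD_partial_then_full_arrest": {"nd_arrest": 0.7, "hsd_arrest": 1.0},
}


def sim_screen(
    gene_table: pd.DataFrame,
    params: PupSimParams | None = None,
    control_label: str = "control",
) -> pd.DataFrame:
    """Simulate a multi-gene screen event table with planted hit classes.

    ``gene_table`` needs columns gene and planted_class (one of the hit-class
    labels or "none"); optional columns excess_delay, nd_delay, hsd_arrest,
    nd_arrest override the class defaults.  A control genotype is always
    simulated alongside.  The screen scores once per day (24 h grid).
    """
    params = params or PupSimParams(obs_interval=24.0)
    unknown = set(gene_table["planted_class"]) - set(HIT_CLASSES)
    if unknown:
        raise ValueError(f"unknown planted class label(s): {sorted(unknown)}")

    rng = np.random.default_rng(params.seed)
    frames = []
    for diet in ("ND", "HSD"):
        frames.append(sim_pupariation(params, control_label, diet, rng=rng))
    for _, row in gene_table.iterrows():
        eff = dict(DEFAULT_CLASS_EFFECTS[row["planted_class"]])
        for key in ("excess_delay", "nd_delay", "hsd_arrest", "nd_arrest"):
            if key in row.index and pd.notna(row.get(key)):
                eff[key] = float(row[key])
        nd_delay = eff.get("nd_delay", 0.0)
        for diet in ("ND", "HSD"):
            arrest = eff.get("hsd_arrest" if diet == "HSD" else "nd_arrest", 0.0)
            p = replace(
                params,
                p50_base=params.p50_base + nd_delay,
                excess_delay=eff.get("excess_delay", 0.0),
                arrest_prob=arrest,
            )
            frames.append(sim_pupariation(p, str(row["gene"]), diet, rng=rng))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "gene", out["genotype"])
    return out


def _grid_dims(n_cells: int) -> tuple[int, int]:
    rows = int(np.floor(np.sqrt(n_cells)))
    while n_cells % rows:
        rows -= 1
    return rows, n_cells // rows


def sim_fatbody_image(params: ImageSimParams) -> tuple[dict[str, np.ndarray], dict]:
    """Simulate a single-plane fat-body field of tiled cells.

    Returns ``(channels, truth)``.  Channels: reporter (cytoplasm level 100,
    membrane = membrane_enrichment x 100), membrane marker, nuclei, droplets.
    Truth contains cell/membrane/droplet boolean masks, nucleus centers, and
    ``nucleus_pairs`` -- adjacent nucleus-center pairs whose connecting line
    crosses a membrane at its midpoint, ready for line-profile quantification.

    The membrane band half-width is 5% of the cell pitch, so the middle tenth
    of a nucleus-to-nucleus profile lies entirely on membrane and the
    flanking tenths entirely on cytoplasm.
    """
    gr, gc = _grid_dims(params.n_cells)
    H, W = params.shape
    pr, pc = H // gr, W // gc
    if min(pr, pc) < 20:
        raise ValueError(
            f"shape {params.shape} too small to place {params.n_cells} cells "
            f"(cell pitch {pr}x{pc} < 20 px)"
        )
    rng = np.random.default_rng(params.seed)
    rr, cc = np.mgrid[0:H, 0:W]

    # distance to nearest internal tile boundary, per axis; membrane bands are
    # centered on pixel column/row k*pitch so a nucleus-to-nucleus line has its
    # midpoint pixel on the membrane
    def boundary_dist(coord: np.ndarray, pitch: int, n_tiles: int) -> np.ndarray:
        d = np.full(coord.shape, np.inf)
        for k in range(1, n_tiles):
            d = np.minimum(d, np.abs(coord - k * pitch))
        return d

    half_r = max(1.0, 0.05 * pr)
    half_c = max(1.0, 0.05 * pc)
    membrane = (boundary_dist(rr, pr, gr) <= half_r) | (boundary_dist(cc, pc, gc) <= half_c)
    # crop to the tiled region (remainder pixels stay background)
    tiled = (rr < gr * pr) & (cc < gc * pc)
    membrane &= tiled
    cell_mask = tiled & ~membrane

    centers = []
    nuclei = np.zeros((H, W), dtype=bool)
    n_rad = max(3, min(pr, pc) // 6)
    for i in range(gr):
        for j in range(gc):
            cy, cx = i * pr + pr // 2, j * pc + pc // 2
            centers.append((cy, cx))
            nuclei |= (rr - cy) ** 2 + (cc - cx) ** 2 <= n_rad**2

    # droplets: disks inside cells until the planted area fraction is reached
    droplets = np.zeros((H, W), dtype=bool)
    if params.droplet_area_fraction > 0:
        d_rad = max(2, min(pr, pc) // 10)
        target = params.droplet_area_fraction * cell_mask.sum()
        interior = cell_mask & ~nuclei
        ys, xs = np.nonzero(interior)
        order = rng.permutation(ys.size)
        k = 0
        while droplets.sum() < target and k < ys.size:
            cy, cx = ys[order[k]], xs[order[k]]
            disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= d_rad**2
            droplets |= disk & cell_mask
            k += 1

    cyto = 100.0
    reporter = np.full((H, W), cyto)
    reporter[membrane] = params.membrane_enrichment * cyto
    reporter[~tiled] = 0.0
    membrane_ch = np.where(membrane, 200.0, 10.0)
    nuclei_ch = np.where(nuclei, 200.0, 10.0)
    droplet_ch = np.where(droplets, 200.0, 10.0)

    channels = {
        "reporter": reporter,
        "membrane": membrane_ch,
        "nuclei": nuclei_ch,
        "droplets": droplet_ch,
    }
    if params.noise_sd > 0:
        for name, img in channels.items():
            channels[name] = np.clip(img + rng.normal(0, params.noise_sd, img.shape), 0, None)

    pairs = []
    for i in range(gr):
        for j in range(gc):
            if j + 1 < gc:
                pairs.append((centers[i * gc + j], centers[i * gc + j + 1]))
            if i + 1 < gr:
                pairs.append((centers[i * gc + j], centers[(i + 1) * gc + j]))

    truth = {
        "cell_mask": cell_mask,
        "membrane_mask": membrane,
        "nuclei_mask": nuclei,
        "droplet_mask": droplets,
        "nucleus_centers": centers,
        "nucleus_pairs": pairs,
        "droplet_area_fraction": droplets.sum() / cell_mask.sum(),
    }
    return channels, truth


def sim_neuron_frames(
    n_neurons: int = 4,
    n_frames: int = 21,
    baseline_ratio: float = 1.0,
    transient_times: Sequence[int] = (),
    transient_amp: float = 0.0,
    kcl_frame: int | None = None,
    kcl_amp: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
) -> tuple[list[dict[str, np.ndarray]], list[np.ndarray], dict]:
    """Simulate a two-channel (gcamp, tdtomato) calcium-imaging frame series.

    The planted per-soma gcamp/tdtomato ratio equals ``baseline_ratio`` except
    at ``transient_times`` (ratio = baseline + transient_amp) and from
    ``kcl_frame`` onward (ratio = baseline + kcl_amp; the depolarisation
    control at the end of a recording).  The tdtomato channel is constant per
    neuron up to noise.  Returns (frames, soma_masks, truth).
    """
    if kcl_frame is not None and not 0 <= kcl_frame < n_frames:
        raise ValueError("kcl_frame out of range")
    for t in transient_times:
        if not 0 <= t < n_frames:
            raise ValueError(f"transient index {t} out of range")
    if kcl_amp is None:
        kcl_amp = 2.0 * baseline_ratio

    rng = np.random.default_rng(seed)
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    rad = max(3, min(H, W) // (3 * n_neurons))
    masks = []
    for k in range(n_neurons):
        cy = H // 2
        cx = int((k + 0.5) * W / n_neurons)
        masks.append((rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2)

    ratio = np.full(n_frames, baseline_ratio)
    for t in transient_times:
        ratio[t] = baseline_ratio + transient_amp
    if kcl_frame is not None:
        ratio[kcl_frame:] = baseline_ratio + kcl_amp

    tdt_level = 100.0
    frames = []
    for f in range(n_frames):
        gc = np.zeros(shape)
        td = np.zeros(shape)
        for m in masks:
            td[m] = tdt_level
            gc[m] = ratio[f] * tdt_level
        if noise_sd > 0:
            gc = np.clip(gc + rng.normal(0, noise_sd, shape), 0, None)
            td = np.clip(td + rng.normal(0, noise_sd, shape), 0, None)
        frames.append({"gcamp": gc, "tdtomato": td})
    truth = {"ratio_series": ratio, "baseline_ratio": baseline_ratio}
    return frames, masks, truth


def sim_phospho(
    params: PhosphoSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate an 18-plex phosphosite quantification table with planted truth.

    Returns ``(table, design, truth)``.  ``table`` holds site_id, protein_id
    and one abundance column per channel; ``design`` maps channel ->
    (genotype, treatment, replicate).  ``truth`` records the planted
    responsive site sets (up/down) per genotype: the control carries the full
    planted response; knockdowns carry it scaled by ``blunting`` (a genotype's
    truth set is empty when the blunted fold change is a no-op).
    """
    rng = np.random.default_rng(params.seed)
    genotypes = ("control", "KD1", "KD2")
    treatments = ("mock", "insulin")

    site_ids = [f"site{i:05d}" for i in range(params.n_sites)]
    protein_ids = [f"prot{i % params.n_proteins:05d}" for i in range(params.n_sites)]

    n_resp = int(round(params.frac_responsive * params.n_sites))
    resp_idx = rng.choice(params.n_sites, size=n_resp, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_resp)
    effect = np.zeros(params.n_sites)
    effect[resp_idx] = signs * params.mean_log2_effect

    base = rng.normal(10.0, 1.0, params.n_sites)

    design_rows = []
    data: dict[str, np.ndarray] = {}
    ch = 0
    for g in genotypes:
        scale = 1.0 if g == "control" else params.blunting
        for tr in treatments:
            for rep in range(1, params.n_replicates + 1):
                ch += 1
                name = f"ch{ch:02d}"
                design_rows.append(
                    {"channel": name, "genotype": g, "treatment": tr, "replicate": rep}
                )
                log2 = base.copy()
                if tr == "insulin":
                    log2 = log2 + scale * effect
                if params.noise_sd > 0:
                    log2 = log2 + rng.normal(0, params.noise_sd, params.n_sites)
                data[name] = 2.0**log2

    table = pd.DataFrame({"site_id": site_ids, "protein_id": protein_ids, **data})
    design = pd.DataFrame(design_rows)

    truth: dict[str, dict[str, set]] = {}
    for g in genotypes:
        scale = 1.0 if g == "control" else params.blunting
        eff = scale * effect
        up = {site_ids[i] for i in np.nonzero(eff > 0)[0]}
        down = {site_ids[i] for i in np.nonzero(eff < 0)[0]}
        truth[g] = {"up": up, "down": down}
    truth_out = {
        "responsive": truth,
        "effect_log2": {site_ids[i]: float(effect[i]) for i in resp_idx},
        "site_to_protein": dict(zip(site_ids, protein_ids)),
    }
    return table, design, truth_out


def sim_plate(
    concentrations: Sequence[float],
    slope: float = 0.002,
    intercept: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_standards: int = 8,
    sample_concs: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Simulate a Beer-Lambert plate: absorbance = intercept + slope x conc + noise.

    Standards span the range of the supplied sample concentrations.  Returns a
    well table (well, role, known_conc, absorbance).
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("empty concentration list")
    rng = np.random.default_rng(seed)
    samples = list(sample_concs) if sample_concs is not None else concentrations
    lo, hi = 0.0, max(max(samples), max(concentrations))
    std_concs = np.linspace(lo, hi, n_standards)

    rows = []
    w = 0
    for c in std_concs:
        w += 1
        a = intercept + slope * c + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append({"well": f"S{w:02d}", "role": "standard", "known_conc": float(c), "absorbance": float(a)})
    for i, c in enumerate(samples, 1):
        a = intercept + slope * c + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append({"well": f"X{i:02d}", "role": "sample", "known_conc": float(c), "absorbance": float(a)})
    return pd.DataFrame(rows)
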