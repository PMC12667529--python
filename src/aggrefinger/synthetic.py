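"""Synthetic single-particle data with exported ground truth.

Every input the fingerprinting pipeline consumes can be generated here:
diffraction-limited TIRF stacks (Gaussian point-spread functions over a
camera-like Poisson + read-noise model), SMLM localization tables sampled
from parametric aggregate shapes (rods and globules) with per-axis precision
jitter, uniform background and optional linear drift, donor cohorts with
disease-direction effects (longer, more eccentric, sparser aggregates in the
TDP-positive cohort), and two-fraction TMT-style protein quantification
tables with spiked enrichments.

All generators are deterministic for a fixed seed and return the ground
truth alongside the data, so downstream recovery tests never peek anywhere
else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOC_COLUMNS = ["frame", "x", "y", "photons", "sx", "sy", "bg", "lpx", "lpy"]

COHORTS = ("CRL", "MND_SOD", "MND_TDP")
REGIONS = ("cerebellum", "frontal_cortex")


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthSpot:
    """True sub-pixel centroid and amplitude of one diffraction-limited punctum."""
    x_px: float
    y_px: float
    amplitude: float
    channel: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("spot amplitude must be positive")


@dataclass
class GroundTruthAggregate:
    """Parametric shape an SMLM localization cloud is sampled from.

    ``length_nm`` is the rod backbone length (ignored for globules, which use
    ``radius_nm``); ``sigma_nm`` is the per-axis localization precision used
    for jitter and written verbatim into the precision columns.
    """
    kind: str = "rod"  # rod | globule
    length_nm: float = 150.0
    radius_nm: float = 50.0
    width_fwhm_nm: float = 20.0
    orientation_rad: float = 0.0
    center_nm: tuple[float, float] = (0.0, 0.0)
    n_localizations: int = 200
    sigma_nm: float = 12.0

    def __post_init__(self) -> None:
        if self.kind not in ("rod", "globule"):
            raise ValueError(f"unknown aggregate kind {self.kind!r}")
        if self.kind == "rod" and self.length_nm <= 0:
            raise ValueError("rod length must be positive")
        if self.kind == "globule" and self.radius_nm <= 0:
            raise ValueError("globule radius must be positive")
        if self.n_localizations < 1:
            raise ValueError("need at least one localization")


# ---------------------------------------------------------------------------
# TIRF stacks
# ---------------------------------------------------------------------------

@dataclass
class TirfSimSpec:
    """Layout and noise model for one simulated field of view.

    ``baseline`` is the constant camera background (photons); shot noise is
    Poisson on the expected photon image and ``read_noise_sd`` adds Gaussian
    camera read noise. With baseline 100 and read noise 2 an amplitude-100
    spot sits at SNR ~ 10.
    """
    width_px: int = 512
    height_px: int = 512
    n_frames: int = 10
    psf_sigma_px: float = 1.3
    baseline: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    spots: list[GroundTruthSpot] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.psf_sigma_px <= 0:
            raise ValueError("PSF sigma must be positive")


def random_spot_layout(n_spots: int, width_px: int, height_px: int,
                       amplitude: float, rng: np.random.Generator,
                       min_separation_px: float = 10.0,
                       margin_px: float = 8.0) -> list[GroundTruthSpot]:
    """Uniform spot positions with a minimum pairwise separation (dart throwing)."""
    spots: list[GroundTruthSpot] = []
    attempts = 0
    while len(spots) < n_spots and attempts < 10000 * n_spots:
        attempts += 1
        x = rng.uniform(margin_px, width_px - margin_px)
        y = rng.uniform(margin_px, height_px - margin_px)
        if all((x - s.x_px) ** 2 + (y - s.y_px) ** 2 >= min_separation_px ** 2
               for s in spots):
            spots.append(GroundTruthSpot(x_px=x, y_px=y, amplitude=amplitude))
    if len(spots) < n_spots:
        raise RuntimeError("could not place requested spots at the given separation")
    return spots


def _render_expected_frame(spec: TirfSimSpec) -> np.ndarray:
    """Noise-free expected photon image: baseline plus one 2-D Gaussian per spot."""
    img = np.full((spec.height_px, spec.width_px), spec.baseline, dtype=float)
    r = int(math.ceil(4 * spec.psf_sigma_px))
    for s in spec.spots:
        x0, y0 = s.x_px, s.y_px
        xi0, yi0 = int(round(x0)), int(round(y0))
        xs = np.arange(max(0, xi0 - r), min(spec.width_px, xi0 + r + 1))
        ys = np.arange(max(0, yi0 - r), min(spec.height_px, yi0 + r + 1))
        if xs.size == 0 or ys.size == 0:
            continue
        gx = np.exp(-0.5 * ((xs - x0) / spec.psf_sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ys - y0) / spec.psf_sigma_px) ** 2)
        img[np.ix_(ys, xs)] += s.amplitude * np.outer(gy, gx)
    return img


def simulate_tirf_stack(spec: TirfSimSpec) -> tuple[np.ndarray, list[GroundTruthSpot]]:
    """Render a multi-frame TIRF acquisition of the spot layout in ``spec``.

    Returns the ``(frames, height, width)`` float stack and the ground-truth
    spot list. Identical specs (including seed) give bit-identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    expected = _render_expected_frame(spec)
    frames = np.empty((spec.n_frames, spec.height_px, spec.width_px), dtype=float)
    for i in range(spec.n_frames):
        frame = rng.poisson(expected).astype(float) if spec.shot_noise else expected.copy()
        if spec.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.read_noise_sd, size=frame.shape)
        frames[i] = frame
    return frames, list(spec.spots)


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------

def _sample_shape_nm(agg: GroundTruthAggregate, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample n true emitter positions (nm, shape-local frame) before jitter."""
    if agg.kind == "rod":
        t = rng.uniform(-agg.length_nm / 2, agg.length_nm / 2, size=n)
        w_sigma = agg.width_fwhm_nm / 2.355  # FWHM -> sigma
        u = rng.normal(0.0, w_sigma, size=n) if w_sigma > 0 else np.zeros(n)
        local = np.column_stack([t, u])
    else:  # uniform disc
        r = agg.radius_nm * np.sqrt(rng.uniform(0, 1, size=n))
        theta = rng.uniform(0, 2 * np.pi, size=n)
        local = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    c, s = math.cos(agg.orientation_rad), math.sin(agg.orientation_rad)
    rot = np.array([[c, -s], [s, c]])
    return local @ rot.T + np.asarray(agg.center_nm)


def simulate_localization_table(
    aggregates: list[GroundTruthAggregate],
    background_rate_per_um2: float = 0.0,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
    n_frames: int = 5000,
    fov_px: tuple[int, int] = (512, 512),
    pixel_size_nm: float = 107.0,
    background_sigma_nm: float = 12.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Localization table for a field of view containing ``aggregates``.

    Emitter positions are sampled along each shape, jittered by the per-axis
    Gaussian precision, assigned uniform random frames, and mixed with a
    Poisson number of uniform background localizations
    (``background_rate_per_um2`` per square micrometre). Linear drift
    accumulates as ``drift * frame`` in camera pixels. Coordinates are camera
    pixels; ``lpx``/``lpy`` carry the jitter sigma (in px) verbatim.

    Returns the table (columns frame, x, y, photons, sx, sy, bg, lpx, lpy)
    and a ground-truth dict with the aggregate list, per-localization labels
    (-1 for background) and the injected drift.
    """
    if background_rate_per_um2 < 0:
        raise ValueError("background rate must be non-negative")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)

    xs, ys, sig, labels = [], [], [], []
    for i, agg in enumerate(aggregates):
        pos = _sample_shape_nm(agg, agg.n_localizations, rng)
        if agg.sigma_nm > 0:
            pos = pos + rng.normal(0.0, agg.sigma_nm, size=pos.shape)
        xs.append(pos[:, 0] / pixel_size_nm)
        ys.append(pos[:, 1] / pixel_size_nm)
        sig.append(np.full(agg.n_localizations, agg.sigma_nm))
        labels.append(np.full(agg.n_localizations, i))

    area_um2 = fov_px[0] * fov_px[1] * (pixel_size_nm / 1000.0) ** 2
    n_bg = rng.poisson(background_rate_per_um2 * area_um2)
    if n_bg:
        xs.append(rng.uniform(0, fov_px[0], size=n_bg))
        ys.append(rng.uniform(0, fov_px[1], size=n_bg))
        sig.append(np.full(n_bg, background_sigma_nm))
        labels.append(np.full(n_bg, -1))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        sigma_nm = np.concatenate(sig)
        label = np.concatenate(labels).astype(int)
    else:
        x = y = sigma_nm = np.empty(0)
        label = np.empty(0, dtype=int)

    n = x.size
    frame = rng.integers(0, n_frames, size=n)
    dx, dy = drift_px_per_frame
    x = x + dx * frame
    y = y + dy * frame

    lp_px = sigma_nm / pixel_size_nm
    table = pd.DataFrame({
        "frame": frame,
        "x": x,
        "y": y,
        "photons": rng.lognormal(math.log(1000.0), 0.3, size=n),
        "sx": np.full(n, 1.3),
        "sy": np.full(n, 1.3),
        "bg": np.full(n, 50.0),
        "lpx": lp_px,
        "lpy": lp_px,
    })
    table.attrs["pixel_size_nm"] = pixel_size_nm
    truth = {
        "aggregates": list(aggregates),
        "labels": label,
        "drift_px_per_frame": (dx, dy),
        "n_background": int(n_bg),
        "n_frames": n_frames,
    }
    return table, truth


# ---------------------------------------------------------------------------
# donor cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Donor-population distributions for one cohort.

    Means are donor-level expectations; ``*_donor_sd`` is the between-donor
    spread. Aggregate-level spread within a donor is fixed (log-normal scale
    0.35 for length, 0.3 for density; normal sd 0.04 for eccentricity,
    0.1 for scaled intensity).
    """
    n_donors: int = 3
    count_mean: float = 300.0
    length_mean_nm: float = 80.0
    length_donor_sd: float = 8.0
    ecc_mean: float = 0.82
    ecc_donor_sd: float = 0.02
    density_mean: float = 0.012
    density_donor_sd: float = 0.0012
    intensity_mean: float = 0.55
    intensity_donor_sd: float = 0.04
    colabel_p: float = 0.15
    colabel_donor_sd: float = 0.03
    region_count_scale: dict = field(default_factory=dict)


@dataclass
class SyntheticCohortSpec:
    """The study design: cohorts x regions x donors x technical replicates.

    Defaults mirror the published design — 3 neurologically normal (CRL),
    2 SOD1-MND and 5 TDP-MND donors, two brain regions, three technical
    replicates — with disease-direction effects: TDP aggregates longer, more
    eccentric and sparser, and counts raised in cerebellum but lowered in
    frontal cortex relative to control.
    """
    cohorts: dict = field(default_factory=lambda: {
        "CRL": CohortParams(),
        "MND_SOD": CohortParams(n_donors=2, length_mean_nm=65.0, ecc_mean=0.76,
                                density_mean=0.016, intensity_mean=0.48,
                                colabel_p=0.10),
        "MND_TDP": CohortParams(n_donors=5, length_mean_nm=130.0, ecc_mean=0.90,
                                density_mean=0.007, intensity_mean=0.62,
                                colabel_p=0.30,
                                region_count_scale={"cerebellum": 1.6,
                                                    "frontal_cortex": 0.7}),
    })
    regions: tuple = REGIONS
    n_replicates: int = 3
    fov_px: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.cohorts.items():
            if p.n_donors < 1:
                raise ValueError(f"cohort {name}: need at least one donor")
            if not 0 <= p.colabel_p <= 1:
                raise ValueError(f"cohort {name}: colabel probability outside [0,1]")


def _donor_params(p: CohortParams, region: str, rng: np.random.Generator) -> dict:
    scale = p.region_count_scale.get(region, 1.0)
    return {
        "count_mean": max(1.0, p.count_mean * scale * rng.normal(1.0, 0.1)),
        "length_mean_nm": max(20.0, rng.normal(p.length_mean_nm, p.length_donor_sd)),
        "ecc_mean": float(np.clip(rng.normal(p.ecc_mean, p.ecc_donor_sd), 0.3, 0.98)),
        "density_mean": max(1e-4, rng.normal(p.density_mean, p.density_donor_sd)),
        "intensity_mean": float(np.clip(rng.normal(p.intensity_mean, p.intensity_donor_sd), 0.05, 0.95)),
        "colabel_p": float(np.clip(rng.normal(p.colabel_p, p.colabel_donor_sd), 0.0, 1.0)),
    }


def _replicate_aggregates(dp: dict, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one replicate's aggregate-level morphometrics from donor parameters.

    Geometry uses the stadium approximation: a rod of backbone length L and
    width w has area L*w + pi*(w/2)^2 and perimeter 2L + pi*w; the ellipse
    axes are L and w.
    """
    length = rng.lognormal(np.log(dp["length_mean_nm"]) - 0.35 ** 2 / 2, 0.35, size=n)
    ecc = np.clip(rng.normal(dp["ecc_mean"], 0.04, size=n), 0.0, 0.995)
    width = np.maximum(length * np.sqrt(1 - ecc ** 2), 8.0)
    area = length * width + np.pi * (width / 2) ** 2
    perimeter = 2 * length + np.pi * width
    density = rng.lognormal(np.log(dp["density_mean"]) - 0.3 ** 2 / 2, 0.3, size=n)
    n_locs = np.maximum(1, np.rint(density * area)).astype(int)
    density = n_locs / area  # density * area == n_locs exactly
    intensity = np.clip(rng.normal(dp["intensity_mean"], 0.1, size=n), 0.0, 1.0)
    colabel = rng.uniform(size=n) < dp["colabel_p"]
    return pd.DataFrame({
        "length_nm": length,
        "eccentricity": ecc,
        "minor_axis_nm": width,
        "major_axis_nm": length,
        "area_nm2": area,
        "perimeter_nm": perimeter,
        "n_localizations": n_locs,
        "density_loc_per_nm2": density,
        "scaled_intensity": intensity,
        "colabel_pser": colabel,
    })


def simulate_cohort(spec: SyntheticCohortSpec,
                    with_localizations: bool = False) -> dict:
    """Generate the full study design from ``spec``.

    Returns a dict with:

    - ``aggregates``: tidy DataFrame, one row per aggregate, with
      morphometrics plus donor/cohort/region/replicate identifiers;
    - ``spots``: per-replicate SpotTable DataFrame (x_px, y_px, intensity,
      colabel flag) concatenated across the design;
    - ``truth``: per-donor parameter table (the ground truth every recovery
      test reads);
    - ``localizations``: {(donor, region, replicate): (table, truth)} when
      ``with_localizations`` is set (rod shapes drawn from the donor's length
      distribution; expensive, off by default).
    """
    rng = np.random.default_rng(spec.seed)
    agg_frames, spot_frames, truth_rows = [], [], []
    locs: dict = {}

    for cohort, params in spec.cohorts.items():
        for d in range(params.n_donors):
            donor_id = f"{cohort}_{d + 1}"
            for region in spec.regions:
                dp = _donor_params(params, region, rng)
                truth_rows.append({"donor": donor_id, "cohort": cohort,
                                   "region": region, **dp})
                for rep in range(spec.n_replicates):
                    n = max(1, rng.poisson(dp["count_mean"]))
                    agg = _replicate_aggregates(dp, n, rng)
                    agg.insert(0, "replicate", rep)
                    agg.insert(0, "region", region)
                    agg.insert(0, "cohort", cohort)
                    agg.insert(0, "donor", donor_id)
                    agg_frames.append(agg)

                    spots = pd.DataFrame({
                        "x_px": rng.uniform(0, spec.fov_px[0], size=n),
                        "y_px": rng.uniform(0, spec.fov_px[1], size=n),
                        "intensity": agg["scaled_intensity"].to_numpy(),
                        "colabel": agg["colabel_pser"].to_numpy(),
                    })
                    spots.insert(0, "replicate", rep)
                    spots.insert(0, "region", region)
                    spots.insert(0, "donor", donor_id)
                    spot_frames.append(spots)

                    if with_localizations:
                        aggs = [GroundTruthAggregate(
                            kind="rod",
                            length_nm=float(L),
                            orientation_rad=rng.uniform(0, np.pi),
                            center_nm=(rng.uniform(5, spec.fov_px[0] - 5) * 107.0,
                                       rng.uniform(5, spec.fov_px[1] - 5) * 107.0),
                            n_localizations=int(nl),
                        ) for L, nl in zip(agg["length_nm"].head(20),
                                           agg["n_localizations"].head(20))]
                        locs[(donor_id, region, rep)] = simulate_localization_table(
                            aggs, fov_px=spec.fov_px,
                            seed=int(rng.integers(2 ** 31)))

    out = {
        "aggregates": pd.concat(agg_frames, ignore_index=True),
        "spots": pd.concat(spot_frames, ignore_index=True),
        "truth": pd.DataFrame(truth_rows),
    }
    if with_localizations:
        out["localizations"] = locs
    return out


def calibrated_cohort_fixture(seed: int = 0,
                              n_donors: int = 10) -> SyntheticCohortSpec:
    """Benchmark cohort with moderate, well-separated effect sizes.

    Used by the discriminant-recovery benchmark: each cohort's donor-level
    means differ by roughly two between-donor standard deviations on the
    disease-direction axes (TDP: longer, more eccentric, sparser; SOD: its
    own shorter/rounder/denser phenotype), so a working signature analysis
    should separate cohorts almost perfectly while noisy donors still
    overlap on any single feature.
    """
    cohorts = {
        "CRL": CohortParams(n_donors=n_donors, length_mean_nm=80.0,
                            length_donor_sd=6.0, ecc_mean=0.82,
                            ecc_donor_sd=0.015, density_mean=0.012,
                            density_donor_sd=0.0008, intensity_mean=0.55,
                            intensity_donor_sd=0.03, colabel_p=0.15),
        "MND_SOD": CohortParams(n_donors=n_donors, length_mean_nm=62.0,
                                length_donor_sd=6.0, ecc_mean=0.75,
                                ecc_donor_sd=0.015, density_mean=0.017,
                                density_donor_sd=0.0008, intensity_mean=0.46,
                                intensity_donor_sd=0.03, colabel_p=0.08),
        "MND_TDP": CohortParams(n_donors=n_donors, length_mean_nm=130.0,
                                length_donor_sd=6.0, ecc_mean=0.90,
                                ecc_donor_sd=0.015, density_mean=0.007,
                                density_donor_sd=0.0008, intensity_mean=0.62,
                                intensity_donor_sd=0.03, colabel_p=0.30,
                                region_count_scale={"cerebellum": 1.6,
                                                    "frontal_cortex": 0.7}),
    }
    return SyntheticCohortSpec(cohorts=cohorts, seed=seed)


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

def simulate_proteomics(
    n_proteins: int = 500,
    n_controls: int = 5,
    n_cases: int = 5,
    enriched: dict | None = None,
    cv: float = 0.10,
    n_contaminants: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two-fraction TMT-style quantification tables with spiked enrichments.

    ``enriched`` maps accession -> (fold in aggregate fraction, fold in total
    proteome) applied to case channels; a protein with equal folds in both
    fractions has corrected ratio 1 by construction. Abundances are
    log-normal with multiplicative noise of coefficient of variation ``cv``.
    The pooled reference column is the per-protein mean over all sample
    channels, mimicking a pooled reference channel.

    Returns (total_table, aggregate_table, truth). Tables are DataFrames with
    accession/peptides/unique_peptides/contaminant metadata, one abundance
    column per channel, reference columns, and attrs ``fraction``,
    ``channels``, ``control_channels``, ``case_channels``, ``reference_map``.
    """
    if n_controls < 2 or n_cases < 2:
        raise ValueError("need at least two controls and two cases")
    if enriched:
        for acc, (ea, et) in enriched.items():
            if ea <= 0 or et <= 0:
                raise ValueError(f"{acc}: folds must be positive")
    rng = np.random.default_rng(seed)
    enriched = enriched or {}

    accessions = [f"P{i:05d}" for i in range(n_proteins)]
    for i in range(min(n_contaminants, n_proteins)):
        accessions[i] = f"CON_{accessions[i]}"
    controls = [f"CRL_{i + 1}" for i in range(n_controls)]
    cases = [f"MND_{i + 1}" for i in range(n_cases)]
    sigma = math.sqrt(math.log(1 + cv ** 2))

    def build(fraction: str) -> pd.DataFrame:
        base = rng.lognormal(math.log(1e6), 1.0, size=n_proteins)
        data = {"accession": accessions,
                "peptides": rng.integers(2, 20, size=n_proteins),
                "unique_peptides": rng.integers(1, 10, size=n_proteins),
                "contaminant": [a.startswith("CON_") for a in accessions]}
        fold_idx = 0 if fraction == "aggregate" else 1
        for ch in controls + cases:
            fold = np.ones(n_proteins)
            if ch in cases:
                for j, acc in enumerate(accessions):
                    if acc in enriched:
                        fold[j] = enriched[acc][fold_idx]
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=n_proteins)
            data[ch] = base * fold * noise
        df = pd.DataFrame(data)
        df["ref_pool"] = df[controls + cases].mean(axis=1)
        df.attrs["fraction"] = fraction
        df.attrs["channels"] = controls + cases
        df.attrs["control_channels"] = controls
        df.attrs["case_channels"] = cases
        df.attrs["reference_map"] = {ch: "ref_pool" for ch in controls + cases}
        return df

    total = build("total")
    aggregate = build("aggregate")
    truth = {
        "enriched": {a: f for a, f in enriched.items() if f[0] / f[1] > 1},
        "depleted": {a: f for a, f in enriched.items() if f[0] / f[1] < 1},
        "contaminants": [a for a in accessions if a.startswith("CON_")],
        "controls": controls,
        "cases": cases,
        "cv": cv,
    }
    return total, aggregate, truth
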