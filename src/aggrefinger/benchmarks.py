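"""Ground-truth recovery benchmarks.

Each routine generates synthetic data with known truth, runs the relevant
pipeline stage, and reports recovery metrics. They back both the package's
validation suite and the reproduction script, and are sized to run on a
single CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import coloc as coloc_mod
from . import detect as detect_mod
from . import lda as lda_mod
from . import morphology as morph
from . import proteomics as prot_mod
from . import stats as stats_mod
from . import subpopulations as subpop_mod
from . import synthetic as syn


def brute_force_dbscan(xy: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """O(n^2) density-reachability reference for DBSCAN semantics.

    Independent of the pipeline's clustering path (no scikit-learn): core
    points are found from the full distance matrix and clusters grown by
    breadth-first density-reachability; noise is -1.
    """
    n = len(xy)
    dist = cdist(xy, xy)
    core = (dist <= eps).sum(axis=1) >= min_samples
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.nonzero(dist[j] <= eps)[0]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels


def detection_recovery(n_seeds: int = 20, n_spots: int = 10,
                       amplitude: float = 100.0, size_px: int = 256,
                       seed: int = 0) -> dict:
    """Detect known spot layouts at SNR ~ 10; pooled recall/precision and
    centroid errors (px)."""
    tp = fp = fn = 0
    errors = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        spots = syn.random_spot_layout(n_spots, size_px, size_px, amplitude, rng)
        stack, truth = syn.simulate_tirf_stack(syn.TirfSimSpec(
            width_px=size_px, height_px=size_px, n_frames=6, spots=spots,
            seed=seed + s))
        det = detect_mod.detect_puncta(detect_mod.mean_projection(stack))
        t = np.array([[sp.x_px, sp.y_px] for sp in truth])
        if len(det):
            d, idx = cKDTree(t).query(det[["x_px", "y_px"]].to_numpy())
            hit = d <= 1.0
            matched = len(set(idx[hit]))
        else:
            hit = np.zeros(0, bool)
            matched = 0
        tp += matched
        fp += int((~hit).sum())
        fn += n_spots - matched
        errors.extend(d[hit].tolist())
    return {"recall": tp / (tp + fn), "precision": tp / (tp + fp),
            "max_centroid_error_px": float(np.max(errors)),
            "mean_centroid_error_px": float(np.mean(errors)),
            "n": n_seeds * n_spots}


def rod_length_recovery(lengths=(50, 100, 150, 200, 300, 400, 500),
                        n_seeds: int = 20, sigma_nm: float = 12.0,
                        seed: int = 0) -> dict:
    """Measure simulated rods; per-length mean recovery ratio, eccentricity,
    and Spearman monotonicity of measured vs true length."""
    rows = []
    for L in lengths:
        for s in range(n_seeds):
            agg = syn.GroundTruthAggregate(
                length_nm=float(L), sigma_nm=sigma_nm,
                n_localizations=max(50, int(2.0 * L)),
                orientation_rad=(seed + s) * 0.37, center_nm=(5000.0, 5000.0))
            table, _ = syn.simulate_localization_table(
                [agg], n_frames=100, seed=seed * 1000 + s * 7 + L)
            xy = table[["x", "y"]].to_numpy()
            mask, _ = morph.regionize_cluster(xy)
            rec = morph.measure_aggregate(mask, xy)
            rows.append({"true_nm": L, "measured_nm": rec.skeleton_length_nm,
                         "eccentricity": rec.eccentricity})
    df = pd.DataFrame(rows)
    per_length = df.groupby("true_nm").agg(
        mean_ratio=("measured_nm", "mean"), mean_ecc=("eccentricity", "mean"))
    per_length["mean_ratio"] /= per_length.index
    rho = sps.spearmanr(df["true_nm"], df["measured_nm"]).statistic
    return {"per_length": per_length, "spearman_rho": float(rho),
            "max_abs_ratio_error": float((per_length["mean_ratio"] - 1).abs().max()),
            "min_mean_ecc_ge_100nm": float(
                per_length.loc[per_length.index >= 100, "mean_ecc"].min()),
            "n": len(df)}


def dbscan_oracle_agreement(n_instances: int = 50, seed: int = 0) -> dict:
    """Cluster random point sets and compare against the density-reachability
    reference label-for-label (up to label permutation)."""
    from sklearn.metrics import adjusted_rand_score
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(10, 200))
        xy = rng.uniform(0, 5, size=(n, 2))
        t = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
        got = morph.cluster_localizations(t, 0.5, 5)
        want = brute_force_dbscan(xy, 0.5, 5)
        same_noise = np.array_equal(got == -1, want == -1)
        if len(set(want)) > 1:
            agree += same_noise and adjusted_rand_score(got, want) == 1.0
        else:
            agree += same_noise
    return {"agreement": agree / n_instances, "n": n_instances}


def coloc_calibration(n_reps: int = 300, seed: int = 0) -> dict:
    """Chance-estimate calibration on independent channels plus recovery of a
    known colabelling probability."""
    rng = np.random.default_rng(seed)
    w, r, n_a, n_b = 512.0, 4.0, 80, 50
    chance = [coloc_mod.chance_coloc_proportion(
        rng.uniform(0, w, size=(n_a, 2)), rng.uniform(0, w, size=(n_b, 2)), w, r)
        for _ in range(n_reps)]
    analytic = 1 - np.exp(-(n_b / w ** 2) * np.pi * r ** 2)

    recovered = []
    for _ in range(20):
        a = rng.uniform(10, w - 10, size=(500, 2))
        col = rng.uniform(size=500) < 0.3
        b = np.vstack([a[col] + rng.normal(0, 0.5, size=(int(col.sum()), 2)),
                       rng.uniform(10, w - 10, size=(30, 2))])
        recovered.append(coloc_mod.coloc_proportion(
            coloc_mod.match_spots(a, b, r)))
    return {"chance_mc": float(np.mean(chance)),
            "chance_analytic": float(analytic),
            "chance_mc_se": float(np.std(chance) / np.sqrt(n_reps)),
            "colabel_recovered": float(np.mean(recovered)),
            "n": n_reps}


def ks_null_calibration(n_comparisons: int = 1000, pop_n: int = 1000,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I rate of the matched-n subsampled KS test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_comparisons):
        a = rng.normal(size=pop_n)
        b = rng.normal(size=pop_n)
        _, p = stats_mod.bootstrap_ks(a, b, subsample_n=1000, n_boot=3, seed=rng)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_comparisons, "n": n_comparisons}


def lda_recovery(seed: int = 0) -> dict:
    """Single-discriminative-feature recovery plus cohort-fixture separation
    (10 donors per cohort, disease-direction effects)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(40, 10))
    labels = np.array(["A"] * 20 + ["B"] * 20)
    x[labels == "B", 4] += 4.0
    res = lda_mod.fit_lda(x, labels, [f"f{i}" for i in range(10)])
    top = lda_mod.rank_contributions(res)["feature"].iloc[0]

    out = syn.simulate_cohort(syn.calibrated_cohort_fixture(seed=seed))
    prof = subpop_mod.build_donor_profiles(out["aggregates"], out["spots"])
    xm, lab, feats = lda_mod.build_feature_matrix(prof)
    fit = lda_mod.fit_lda(xm, lab, feats)
    acc = lda_mod.loo_nearest_centroid_accuracy(
        xm, lab, group_by=prof["cohort"].to_numpy())
    return {"single_feature_evr": float(res.explained_variance_ratio[0]),
            "top_feature_correct": top == "f4",
            "loo_accuracy": float(acc),
            "cohort_ld1_evr": float(fit.explained_variance_ratio[0]),
            "cohort_ld2_evr": float(fit.explained_variance_ratio[1]),
            "n": len(prof)}


def proteomics_recovery(n_sims: int = 100, cv: float = 0.10,
                        seed: int = 0) -> dict:
    """Spike-in recovery (log2 fold 2) and null false-call rate over repeated
    simulated experiments."""
    logs, correct, false_rates = [], 0, []
    enriched = {"P00050": (4.0, 1.0), "P00051": (0.25, 1.0)}
    for s in range(n_sims):
        total, agg, truth = syn.simulate_proteomics(
            n_proteins=100, enriched=enriched, cv=cv, seed=seed * 1009 + s)
        total = prot_mod.reference_normalize(prot_mod.filter_quantified(total))
        agg = prot_mod.reference_normalize(prot_mod.filter_quantified(agg))
        v = prot_mod.volcano_classify(prot_mod.compute_corrected_ratios(
            total, agg, truth["controls"], truth["cases"])).set_index("accession")
        logs.append(v.loc["P00050", "mean_log2_corrected"])
        correct += (v.loc["P00050", "call"] == "enriched" and
                    v.loc["P00051", "call"] == "depleted")
        false_rates.append(
            (v.drop(["P00050", "P00051"])["call"] != "ns").mean())
    return {"mean_log2_corrected": float(np.mean(logs)),
            "call_accuracy": correct / n_sims,
            "null_false_call_rate": float(np.mean(false_rates)),
            "n": n_sims}


def drift_recovery(rate_px_per_frame: tuple[float, float] = (0.002, 0.001),
                   n_frames: int = 5000, seed: int = 0) -> dict:
    """Recover injected linear drift; relative error of the terminal
    displacement on each axis."""
    rng = np.random.default_rng(seed)
    aggs = [syn.GroundTruthAggregate(
        length_nm=float(rng.uniform(100, 300)), n_localizations=400,
        center_nm=(rng.uniform(40, 140) * 107.0, rng.uniform(40, 140) * 107.0),
        orientation_rad=rng.uniform(0, np.pi)) for _ in range(4)]
    table, _ = syn.simulate_localization_table(
        aggs, background_rate_per_um2=0.05,
        drift_px_per_frame=rate_px_per_frame, n_frames=n_frames, seed=seed)
    _, trace = morph.estimate_and_correct_drift(table, 10)
    span = trace["frame"].iloc[-1] - trace["frame"].iloc[0]
    errs = []
    for axis, rate in zip(("dx_px", "dy_px"), rate_px_per_frame):
        est_rate = (trace[axis].iloc[-1] - trace[axis].iloc[0]) / span
        errs.append(abs(est_rate - rate) / rate)
    return {"terminal_error_frac": float(max(errs)),
            "terminal_displacement_px": float(
                max(abs(r) * n_frames for r in rate_px_per_frame)),
            "n": len(table)}
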