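"""Ground-truth recovery benchmarks.

Because the package's inputs are synthetic scenes and tables with
known generating parameters, every layer can be scored against exact
ground truth.  This module bundles those end-to-end checks — analytic
eccentricity recovery, segmentation truth recovery, closed-form and
cross-implementation GLM agreement, mixed-model parameter recovery,
test calibration, and dose–response recovery through the full
pipeline — so they can be run from the test suite or scripted as a
reproducibility report.  Every stochastic benchmark takes an explicit
seed.
"""

from __future__ import annotations

import math
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit

from .glm import ModelSpec, build_design, fit_binomial_glm, fit_quasipoisson_glm
from .glmm import fit_binomial_glmm
from .metrics import SIZE_CLASS_BOUNDS, SIZE_CLASS_NAMES, classify_myotube_size, fusion_index
from .pipeline import RunConfig, run
from .segment import compute_eccentricity, segment_frame
from .simulate import OutcomeTableSpec, SceneParams, generate_outcomes, generate_scene


def rasterize_ellipse(a: float, b: float, theta: float = 0.0,
                      pad: int = 8) -> np.ndarray:
    """Boolean raster of a filled ellipse with semi-axes a ≥ b."""
    n = int(2 * a) + 2 * pad
    c = n / 2.0
    yy, xx = np.mgrid[:n, :n]
    x = (xx - c) * math.cos(theta) + (yy - c) * math.sin(theta)
    y = -(xx - c) * math.sin(theta) + (yy - c) * math.cos(theta)
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def eccentricity_oracle(axis_ratios=(1.0, 0.8, 0.6, 0.5, 0.25),
                        n_rotations: int = 8, b: float = 20.0) -> dict:
    """Moment eccentricity of rasterized ellipses vs. the analytic value.

    For each axis ratio and rotation, compares e(raster) with
    sqrt(1 − (b/a)²).  Returns the worst absolute error and case count.
    """
    errors = []
    for ratio in axis_ratios:
        a = b / ratio
        expected = math.sqrt(1.0 - ratio**2)
        for ang in np.linspace(0.0, math.pi, n_rotations, endpoint=False):
            e = compute_eccentricity(rasterize_ellipse(a, b, ang))
            errors.append(abs(e - expected))
    return {
        "max_abs_error": float(max(errors)),
        "n_cases": len(errors),
        "n_within_002": int(sum(err <= 0.02 for err in errors)),
    }


def _benchmark_scene(seed: int, n_cells: int = 100) -> SceneParams:
    return SceneParams(
        n_cells=n_cells, myotube_fraction=0.15,
        marker_probs={"myhc": 0.1}, background_amplitude=0.3,
        speckle_density=5.0, seed=seed,
    )


def _assignment_accuracy(scene, seg) -> float:
    """Fraction of nuclei whose segmented cell reproduces the truth cell.

    Detected nuclei are matched to truth nuclei by nearest centre
    (within 3 px).  A nucleus counts as correctly assigned when its
    segmented cell contains exactly the nuclei of its truth cell — no
    splits, merges or strays.
    """
    truth_pts, truth_cell = [], []
    for c in scene.cells:
        for p in c.nuclei:
            truth_pts.append(p)
            truth_cell.append(c.cell_id)
    truth_pts = np.asarray(truth_pts)
    truth_cell = np.asarray(truth_cell)
    n_truth = len(truth_pts)
    if n_truth == 0:
        return 100.0

    ids = [int(l) for l in np.unique(seg.nucleus_labels) if l > 0]
    cents = np.asarray(
        ndi.center_of_mass(seg.nucleus_labels > 0, seg.nucleus_labels, ids)
    )
    det = []
    for lab, ctr in zip(ids, cents):
        d = np.linalg.norm(truth_pts - ctr, axis=1)
        j = int(d.argmin())
        matched_truth = int(truth_cell[j]) if d[j] <= 3.0 else -1
        overlap = seg.cell_labels[seg.nucleus_labels == lab]
        overlap = overlap[overlap > 0]
        det_cell = int(np.bincount(overlap).argmax()) if overlap.size else 0
        det.append((lab, matched_truth, det_cell))
    df = pd.DataFrame(det, columns=["nuc", "truth_cell", "det_cell"])
    truth_sizes = {c.cell_id: c.n_nuclei for c in scene.cells}

    correct = 0
    for det_cell, sub in df.groupby("det_cell"):
        if det_cell == 0:
            continue
        tcs = sub["truth_cell"].unique()
        if len(tcs) == 1 and tcs[0] != -1 and len(sub) == truth_sizes.get(tcs[0]):
            correct += len(sub)
    return 100.0 * correct / n_truth


def segmentation_recovery(scene_seeds=range(1, 21), n_cells: int = 100) -> dict:
    """Nucleus counts, nucleus→cell assignment and fusion index vs. truth.

    Generates one benchmark scene per seed (background gradient 0.3,
    5 speckles per megapixel) and runs the default segmentation.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in scene_seeds:
            scene = generate_scene(_benchmark_scene(seed, n_cells))
            seg = segment_frame(scene.frame)
            n_truth = int(scene.truth_table["n_nuclei"].sum())
            fi = fusion_index(seg.to_table(), total_nuclei=seg.n_nuclei_total)
            rows.append(
                {
                    "seed": seed,
                    "nucleus_count_error_pct":
                        100.0 * abs(seg.n_nuclei_total - n_truth) / n_truth,
                    "assignment_accuracy_pct": _assignment_accuracy(scene, seg),
                    "fusion_abs_error": abs(fi.ratio - scene.true_fusion_index),
                }
            )
    per_scene = pd.DataFrame(rows)
    return {
        "max_nucleus_count_error_pct": float(per_scene["nucleus_count_error_pct"].max()),
        "min_assignment_accuracy_pct": float(per_scene["assignment_accuracy_pct"].min()),
        "max_fusion_abs_error": float(per_scene["fusion_abs_error"].max()),
        "n_scenes": len(per_scene),
        "per_scene": per_scene,
    }


def saturated_glm_oracle() -> dict:
    """Saturated factorial fits vs. closed-form cell contrasts.

    On a saturated design the binomial ML coefficients are exact
    log-odds contrasts of the cell proportions, and the quasi-Poisson
    coefficients exact log contrasts of the cell means.
    """
    # binomial 2x2
    data = pd.DataFrame(
        {"A": [0, 1, 0, 1], "B": [0, 0, 1, 1],
         "s": [50, 25, 50, 75], "n": [100, 100, 100, 100]}
    )
    spec = ModelSpec("binomial-grouped", ("s", "n"),
                     factors=["A", "B"], interactions=[("A", "B")])
    d = build_design(spec, data)
    fit = fit_binomial_glm(d.X, d.y, d.trials)
    logit = lambda p: math.log(p / (1 - p))
    expected = np.array(
        [logit(0.50), logit(0.25) - logit(0.50), logit(0.50) - logit(0.50),
         logit(0.75) - logit(0.25) - logit(0.50) + logit(0.50)]
    )
    err_b = np.max(np.abs(fit.params.to_numpy() - expected))

    # quasi-Poisson, two conditions: coefficients are log cell-mean contrasts
    counts = pd.DataFrame(
        {"g": [0] * 4 + [1] * 4, "count": [8, 12, 9, 11, 18, 22, 19, 21]}
    )
    spec_q = ModelSpec("count", "count", factors=["g"])
    dq = build_design(spec_q, counts)
    fq = fit_quasipoisson_glm(dq.X, dq.y)
    m0 = counts.loc[counts.g == 0, "count"].mean()
    m1 = counts.loc[counts.g == 1, "count"].mean()
    err_q = max(abs(fq.params.iloc[0] - math.log(m0)),
                abs(fq.params.iloc[1] - (math.log(m1) - math.log(m0))))
    return {"max_abs_error": float(max(err_b, err_q)), "n": len(data) + len(counts)}


def glm_crosscheck(seed: int = 0, n_problems: int = 10) -> dict:
    """Coefficients and SEs vs. an independent reference implementation.

    Fits random full-rank binomial and quasi-Poisson problems with this
    package and with statsmodels and returns the largest absolute
    difference across all coefficients and standard errors.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_problems):
        n, p = 40, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta = rng.normal(scale=0.5, size=p)
        if k % 2 == 0:
            trials = rng.integers(20, 60, n).astype(float)
            y = rng.binomial(trials.astype(int), expit(X @ beta)).astype(float)
            mine = fit_binomial_glm(X, y, trials)
            ref = sm.GLM(np.column_stack([y, trials - y]), X,
                         family=sm.families.Binomial()).fit()
        else:
            y = rng.poisson(np.exp(X @ beta * 0.5 + 1.5)).astype(float)
            mine = fit_quasipoisson_glm(X, y)
            ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
        worst = max(
            worst,
            float(np.max(np.abs(mine.params.to_numpy() - ref.params))),
            float(np.max(np.abs(mine.se.to_numpy() - ref.bse))),
        )
    return {"max_abs_diff": worst, "n_problems": n_problems}


def glmm_recovery(seed: int = 0, n_reps: int = 50) -> dict:
    """Fixed-effect recovery of the random-intercept logistic model.

    Replicates of µ = −1, β = 1.5, σ_g = 0.7 with 10 groups × 500
    cells per condition; reports the absolute bias of the mean fixed
    effects and the 95% Wald CI coverage of β.
    """
    rng = np.random.default_rng(seed)
    mus, betas, covered = [], [], []
    for _ in range(n_reps):
        spec = OutcomeTableSpec(
            factors=["trt"], mu=-1.0, beta={"trt": 1.5}, n_groups=10,
            random_sd=0.7, cells_per_group_per_condition=500,
            seed=int(rng.integers(2**31 - 1)),
        )
        df = generate_outcomes(spec)
        ms = ModelSpec("binomial-bernoulli", "outcome", factors=["trt"],
                       random_intercept="mouse")
        d = build_design(ms, df)
        fit = fit_binomial_glmm(d.X, d.y, d.groups)
        mus.append(fit.params["(Intercept)"])
        betas.append(fit.params["trt[1]"])
        se_b = fit.se["trt[1]"]
        covered.append(abs(betas[-1] - 1.5) <= 1.96 * se_b)
    bias_mu = abs(float(np.mean(mus)) - (-1.0))
    bias_beta = abs(float(np.mean(betas)) - 1.5)
    return {
        "bias_mu": bias_mu, "bias_beta": bias_beta,
        "mean_abs_bias": max(bias_mu, bias_beta),
        "coverage_beta_pct": 100.0 * float(np.mean(covered)),
        "n_reps": n_reps,
    }


def interaction_type1(seed: int = 0, n_reps: int = 2000,
                      n_per_cell: int = 100, p0: float = 0.4) -> dict:
    """Empirical size of the Wald interaction test under the null.

    Saturated 2×2 binomial designs with no true interaction; reports
    the fraction of replicates with interaction p < 0.05.
    """
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({"A": [0, 1, 0, 1], "B": [0, 0, 1, 1]})
    spec = ModelSpec("binomial-grouped", ("s", "n"),
                     factors=["A", "B"], interactions=[("A", "B")])
    rejections = 0
    done = 0
    for _ in range(n_reps):
        d = data.copy()
        d["s"] = rng.binomial(n_per_cell, p0, 4)
        d["n"] = n_per_cell
        if (d["s"] == 0).any() or (d["s"] == n_per_cell).any():
            continue  # saturated fit undefined at the boundary
        des = build_design(spec, d)
        fit = fit_binomial_glm(des.X, des.y, des.trials)
        p = fit.summary().loc["A[1]:B[1]", "p"]
        rejections += p < 0.05
        done += 1
    return {"type1_rate": rejections / done, "n_reps": done}


def size_class_partition(n_max: int = 100) -> dict:
    """Exhaustive check that the size classes partition 2..n_max."""
    violations = 0
    for n in range(2, n_max + 1):
        hits = []
        for name in SIZE_CLASS_NAMES:
            lo, hi = SIZE_CLASS_BOUNDS[name]
            if lo <= n and (hi is None or n <= hi):
                hits.append(name)
        if len(hits) != 1 or classify_myotube_size(n) != hits[0]:
            violations += 1
    return {"violations": violations, "n_checked": n_max - 1}


def dose_response_recovery(seed: int = 0, mu: float = -1.2, c: float = 0.5,
                           doses=(0.0, 1.0, 2.0, 3.0), n_groups: int = 3,
                           random_sd: float = 0.2, n_frames: int = 2,
                           outdir: str | Path | None = None) -> dict:
    """End-to-end dose recovery through simulate → segment → metrics → fit.

    Each nucleus fuses with probability logistic(µ + c·dose + u_g);
    scenes are rendered, segmented, and the measured per-scene fused /
    total counts fitted with a dose-slope logistic model with a random
    group intercept.  Reports the fitted slope, its SE and the z-score
    against the programmed value.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, random_sd, n_groups)
    grid = []
    for gi in range(n_groups):
        for dose in doses:
            p = float(expit(mu + c * dose + u[gi]))
            grid.append(
                {"condition": "dose_series", "dose": dose,
                 "groups": [f"m{gi + 1}"], "n_frames": n_frames,
                 "scene": {"fusion_probability": p}}
            )
    config = RunConfig(
        seed=int(rng.integers(2**31 - 1)),
        stages=("simulate", "segment", "metrics", "fit"),
        scene={"n_cells": 150, "marker_probs": {"myhc": 0.1},
               "myotube_fraction": 0.0},
        grid=grid,
        model={"response_kind": "binomial-grouped", "response": ["fused", "total"],
               "dose_term": "dose", "random_intercept": "group"},
    )
    import json

    def _run_into(target) -> tuple[float, float]:
        manifest = run(config, target)
        c_hat = manifest["stages"]["fit"]["coefficients"]["dose"]
        payload = json.loads(
            (Path(manifest["stages"]["fit"]["report_dir"]) / "fit.json").read_text()
        )
        return float(c_hat), float(payload["se"]["dose"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if outdir is None:
            with tempfile.TemporaryDirectory() as tmp:
                c_hat, se = _run_into(tmp)
        else:
            c_hat, se = _run_into(outdir)
    return {
        "c_hat": float(c_hat), "c_true": float(c), "se": float(se),
        "z_vs_truth": float((c_hat - c) / se),
        "sign_correct": bool(np.sign(c_hat) == np.sign(c)),
        "n_scenes": len(doses) * n_groups * n_frames,
    }
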