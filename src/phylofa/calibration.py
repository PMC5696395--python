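"""Simulation-based self-calibration experiments.

Each function runs a statistical validation experiment for the signal
machinery under known ground truth — exactness on star trees, type-I error
of the permutation null, calibration of K under Brownian motion, λ recovery,
and end-to-end signal detection on synthetic compositional tables — and
returns the measured quantities. They are used by the test suite and by the
reproducibility script; all randomness is controlled by a single seed.
"""

from __future__ import annotations

import numpy as np

from . import fa, signal as sig
from .pipeline import AnalysisConfig, analyze
from .synthetic import SyntheticSpec, simulate_lambda_traits, synthetic_fa_table, yule_tree
from .tree import parse_newick, phylo_covariance, simulate_bm

__all__ = [
    "star_k_max_error",
    "bm_calibration",
    "permutation_type_i_error",
    "lambda_recovery",
    "end_to_end_recovery",
]


def star_k_max_error(n_tips: int = 12, n_traits: int = 50, seed: int = 0) -> float:
    """Max |K − 1| over random traits on an equal-depth star tree.

    On a star tree the Brownian covariance is proportional to the identity,
    so K equals 1 analytically for every non-constant trait.
    """
    nwk = "(" + ",".join(f"t{i}:1" for i in range(n_tips)) + ");"
    cov = phylo_covariance(parse_newick(nwk))
    rng = np.random.default_rng(seed)
    errs = [
        abs(sig.blomberg_k(rng.standard_normal(n_tips), cov).K - 1.0)
        for _ in range(n_traits)
    ]
    return float(max(errs))


def bm_calibration(
    n_tips: int = 50,
    n_traits: int = 1000,
    n_null: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """K of Brownian traits against the BM simulation null, on one Yule tree.

    Returns the median K over ``n_traits`` independent BM traits and the
    fraction classified outside the [2.5%, 97.5%] log-K band of an
    independent ``n_null``-trait simulated null (nominally 5%).
    """
    rng = np.random.default_rng(seed)
    tree = yule_tree(n_tips, seed=rng)
    cov = phylo_covariance(tree)
    X = simulate_bm(tree, 1.0, n_traits, seed=rng)
    K = sig._k_batch(X, cov.C)
    null = np.log(sig._k_batch(simulate_bm(tree, 1.0, n_null, seed=rng), cov.C))
    q025, q975 = np.quantile(null, [0.025, 0.975])
    logK = np.log(K)
    flagged = float(np.mean((logK < q025) | (logK > q975)))
    return {"median_k": float(np.median(K)), "flagged_fraction": flagged}


def permutation_type_i_error(
    n_tips: int = 50,
    n_traits: int = 1000,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the permutation K test on white-noise traits.

    Traits carry no phylogenetic structure, so the rejection fraction at
    level ``alpha`` estimates the test's type-I error.
    """
    rng = np.random.default_rng(seed)
    tree = yule_tree(n_tips, seed=rng)
    cov = phylo_covariance(tree)
    rejections = 0
    for _ in range(n_traits):
        x = rng.standard_normal(n_tips)
        p = sig.permutation_test_k(x, None, cov, n_perm=n_perm, seed=rng)
        rejections += p < alpha
    return rejections / n_traits


def lambda_recovery(
    lam_true_values=(0.0, 0.5, 1.0),
    n_tips: int = 100,
    n_traits: int = 200,
    seed: int = 0,
) -> dict[float, float]:
    """Mean ML λ̂ per true λ on traits simulated with λ-structured covariance."""
    rng = np.random.default_rng(seed)
    tree = yule_tree(n_tips, seed=rng)
    cov = phylo_covariance(tree)
    out = {}
    for lam_true in lam_true_values:
        X = simulate_lambda_traits(tree, lam_true, 1.0, n_traits, seed=rng)
        hats = [
            sig.pagel_lambda_ml(X[:, j], cov=cov, lam_max=1.0).lam_hat
            for j in range(n_traits)
        ]
        out[float(lam_true)] = float(np.mean(hats))
    return out


def end_to_end_recovery(
    n_seeds: int = 100,
    n_perm: int = 199,
    n_sim: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Full-pipeline signal detection rates on default synthetic tables.

    For each generator seed a fresh tree and replicate-level FA table are
    produced at the default study scale (40 species, 3 replicates), the
    whole analysis is run, and individual-FA decisions are scored against
    the generator's ground truth. Returns the detection rate among
    phylogenetically conserved FAs and the false-positive rate among labile
    FAs, pooled over seeds.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_seeds)
    cons_hits = cons_total = lab_hits = lab_total = 0
    for child in children:
        gen_seed = int(child.generate_state(1)[0] % (2**31))
        spec = SyntheticSpec(seed=gen_seed)
        tree = yule_tree(spec.n_species, spec.birth_rate, seed=spec.seed)
        table, truth = synthetic_fa_table(spec, tree)
        cfg = AnalysisConfig(n_perm=n_perm, n_sim=n_sim, alpha=alpha, seed=gen_seed)
        rep = analyze(tree, table, cfg)
        fa_rows = rep.report[rep.report.family == "fa"].set_index("trait")
        for trait, present in fa_rows["signal_present"].items():
            lam_true = truth.lambda_true.get(trait)
            if lam_true == 1.0:
                cons_total += 1
                cons_hits += bool(present)
            elif lam_true == 0.0:
                lab_total += 1
                lab_hits += bool(present)
    return {
        "conserved_detection_rate": cons_hits / cons_total,
        "labile_false_positive_rate": lab_hits / lab_total,
        "n_conserved": cons_total,
        "n_labile": lab_total,
    }
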