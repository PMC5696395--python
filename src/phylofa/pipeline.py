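"""End-to-end analysis: preprocessing → ordination → signal suite → report.

Mirrors the study workflow: rare-FA elimination and renormalization, logit
transform, species means with standard errors, eigen-PCA with broken-stick
axis retention, FA–PC correlations, FA indices, then — for three trait
families (species PC scores, individual FA proportions, FA indices) —
Blomberg's K with measurement error, the tip-permutation null, the
BM-simulation null for significant K values, Pagel's λ with a likelihood
ratio test, Benjamini–Hochberg adjustment within each family, and the
dual-criterion signal decision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fa, ordination, signal as sig
from .tree import Phylogeny, normalize_label, phylo_covariance, lambda_max, prune_to_taxa, read_newick

__all__ = ["AnalysisConfig", "AnalysisReport", "analyze", "run_analysis", "REPORT_COLUMNS"]

REPORT_COLUMNS = [
    "family", "trait", "K", "p_perm", "p_perm_BH", "p_sim", "simK_q025", "simK_q975",
    "bm_class", "lambda", "logL", "logL0", "p_lr", "p_lr_BH", "signal_present",
    "lambda_at_bound",
]


@dataclass
class AnalysisConfig:
    """All knobs of one analysis run.

    Defaults follow the reference workflow: 1% abundance / two-measurement
    rare-FA rules, adjusted-logit eps 0.025, 10,000 tip permutations, 5,000
    BM simulations, α = 0.05, BH adjustment within each trait family.
    """

    tree_path: str | None = None
    table_path: str | None = None
    literature_paths: tuple[str, ...] = ()
    mode: str = "field"  # field | combined
    min_pct: float = 1.0
    min_occurrence: int = 2
    eps: float = 0.025
    n_perm: int = 10000
    n_sim: int = 5000
    alpha: float = 0.05
    n_axes_override: int | None = None
    use_se_in_sim: bool = False
    allow_prune: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.n_perm, self.n_sim, self.min_occurrence) < 1:
            raise ValueError("counts must be positive")
        if self.mode not in ("field", "combined"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class AnalysisReport:
    """Everything one run produced, machine-readable."""

    report: pd.DataFrame
    pca: ordination.PCAResult
    retained_axes: list[int]
    correlations: pd.DataFrame
    dropped_fas: dict[str, str]
    species_means: pd.DataFrame
    config: AnalysisConfig
    log: list[str] = field(default_factory=list)


def _reconcile(tree: Phylogeny, table: pd.DataFrame, allow_prune: bool, log: list[str]):
    table = table.copy()
    table["species"] = [normalize_label(s) for s in table["species"]]
    table_sp = set(table["species"])
    tips = set(tree.tip_names)
    extra_rows = sorted(table_sp - tips)
    extra_tips = sorted(tips - table_sp)
    if extra_rows or extra_tips:
        if not allow_prune:
            raise ValueError(
                "species/tip mismatch: in table but not tree "
                f"{extra_rows}; in tree but not table {extra_tips} (set allow_prune to proceed)"
            )
        if extra_rows:
            log.append(f"excluded from signal (not in tree): {extra_rows}")
            table = table[~table["species"].isin(extra_rows)]
        if extra_tips:
            log.append(f"pruned tips without measurements: {extra_tips}")
    keep = sorted(set(table["species"]))
    if len(keep) < 3:
        raise ValueError("fewer than 3 species shared between tree and table")
    if set(tree.tip_names) != set(keep):
        tree = prune_to_taxa(tree, keep)
    return tree, table


def _signal_family(
    family: str,
    means: pd.DataFrame,
    ses: pd.DataFrame,
    tree: Phylogeny,
    cov,
    lmax: float,
    cfg: AnalysisConfig,
    seedseq: np.random.SeedSequence,
    log: list[str],
) -> list[dict]:
    rows = []
    taxa = list(cov.taxa)
    children = seedseq.spawn(len(means.columns))
    for child, trait in zip(children, means.columns):
        x_full = means[trait].reindex(taxa)
        se_full = ses[trait].reindex(taxa)
        ok = x_full.notna()
        if ok.sum() < 3 or np.ptp(x_full[ok].to_numpy()) == 0:
            log.append(f"{family}/{trait}: skipped (constant or <3 defined species)")
            continue
        if not ok.all():
            log.append(f"{family}/{trait}: dropped species with undefined value: {list(x_full.index[~ok])}")
        sub = sorted(x_full.index[ok])
        c = cov.submatrix(sub) if len(sub) < len(taxa) else cov
        subtree = prune_to_taxa(tree, sub) if len(sub) < len(taxa) else tree
        x = x_full[sub].to_numpy(dtype=float)
        se = se_full[sub].fillna(0.0).to_numpy(dtype=float)
        perm_rng, sim_rng = (np.random.default_rng(s) for s in child.spawn(2))
        k = sig.blomberg_k_with_se(x, se, c)
        k.p_perm = sig.permutation_test_k(x, se, c, n_perm=cfg.n_perm, seed=perm_rng)
        if k.p_perm < cfg.alpha:
            k.p_sim, k.sim_q025, k.sim_q975, k.bm_class = sig.bm_simulation_test(
                k.K, subtree, n_sim=cfg.n_sim, seed=sim_rng,
                se=se if cfg.use_se_in_sim else None,
            )
        lam = sig.pagel_lambda_ml(x, cov=c, lam_max=lmax)
        rows.append({"family": family, "trait": trait, "_k": k, "_lam": lam})
    if not rows:
        return []
    p_perm_adj = sig.bh_adjust([r["_k"].p_perm for r in rows])
    p_lr_adj = sig.bh_adjust([r["_lam"].p_lr for r in rows])
    out = []
    for row, pa, la in zip(rows, p_perm_adj, p_lr_adj):
        k, lam = row["_k"], row["_lam"]
        k.p_perm_adj, lam.p_lr_adj = float(pa), float(la)
        decision = sig.dual_decision(k, lam, alpha=cfg.alpha)
        out.append(
            {
                "family": row["family"], "trait": row["trait"], "K": k.K,
                "p_perm": k.p_perm, "p_perm_BH": k.p_perm_adj,
                "p_sim": k.p_sim, "simK_q025": k.sim_q025, "simK_q975": k.sim_q975,
                "bm_class": k.bm_class,
                "lambda": lam.lam_hat, "logL": lam.logL, "logL0": lam.logL0,
                "p_lr": lam.p_lr, "p_lr_BH": lam.p_lr_adj,
                "signal_present": decision.signal_present,
                "lambda_at_bound": lam.at_upper_bound,
            }
        )
    return out


def analyze(
    tree: Phylogeny,
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    literature: list[pd.DataFrame] | None = None,
) -> AnalysisReport:
    """Run the full signal analysis on an in-memory tree and FA table."""
    cfg = config or AnalysisConfig()
    log: list[str] = [f"config: {dataclasses.asdict(cfg)}"]
    if cfg.mode == "combined":
        table, dropped = fa.merge_literature(
            table, literature or [], min_pct=cfg.min_pct, min_occurrence=cfg.min_occurrence
        )
    else:
        table, dropped = fa.filter_rare(table, min_pct=cfg.min_pct, min_occurrence=cfg.min_occurrence)
        table = fa.renormalize(table)
    if dropped:
        log.append(f"dropped FAs: {dropped}")
    tree, table = _reconcile(tree, table, cfg.allow_prune, log)

    logit = fa.logit_table(table, eps=cfg.eps)
    stats = fa.species_stats(logit)
    single = stats.n_obs[stats.n_obs == 1]
    if len(single):
        log.append(f"single-measurement species (se = 0): {list(single.index)}")

    pca = ordination.pca_species_means(stats.mean)
    retained = ordination.select_axes(pca)
    log.append(f"broken-stick retained axes: {retained}")
    if cfg.n_axes_override is not None:
        retained = list(range(1, cfg.n_axes_override + 1))
        log.append(f"axis override in effect: {retained}")
    elif not retained:
        retained = [1]
        log.append("no axis beat the broken stick; reporting PC1 only")
    pc_cols = [f"PC{k}" for k in retained]
    obs_scores = ordination.project(pca, logit)
    obs_scores.insert(0, "species", logit["species"].to_numpy())
    score_stats = fa.species_stats(obs_scores, value_columns=pc_cols)
    correlations = ordination.correlate_with_axes(
        stats.mean, pca.species_scores[pc_cols]
    )

    fa_cols = fa.fa_columns(table)
    idx = table.apply(lambda r: fa.compute_indices(r[fa_cols]), axis=1)
    idx.insert(0, "species", table["species"].to_numpy())
    idx_stats = fa.species_stats(idx, value_columns=[c for c in idx.columns if c != "species"])

    cov = phylo_covariance(tree)
    lmax = lambda_max(tree)
    log.append(f"lambda search ceiling lambda_max = {lmax:.6g}")
    root = np.random.SeedSequence(cfg.seed)
    fam_seeds = root.spawn(3)
    parts = [
        _signal_family("pc_scores", score_stats.mean, score_stats.se, tree, cov, lmax, cfg, fam_seeds[0], log),
        _signal_family("fa", stats.mean, stats.se, tree, cov, lmax, cfg, fam_seeds[1], log),
        _signal_family("index", idx_stats.mean, idx_stats.se, tree, cov, lmax, cfg, fam_seeds[2], log),
    ]
    rows = [row for part in parts for row in part]
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return AnalysisReport(
        report=report, pca=pca, retained_axes=retained, correlations=correlations,
        dropped_fas=dropped, species_means=stats.mean, config=cfg, log=log,
    )


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """File-based entry point: read tree and table(s), analyze, write reports."""
    if not config.tree_path or not config.table_path:
        raise ValueError("tree_path and table_path are required")
    tree = read_newick(config.tree_path)
    table = _read_table(config.table_path)
    literature = [_read_table(p) for p in config.literature_paths]
    result = analyze(tree, table, config, literature=literature)
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def _write_outputs(result: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rounded = result.report.copy()
    for c in rounded.columns:
        if rounded[c].dtype.kind == "f":
            rounded[c] = rounded[c].round(3)
    rounded.to_csv(outdir / "report.tsv", sep="\t", index=False)
    result.report.to_csv(outdir / "report_full.tsv", sep="\t", index=False)
    pca = result.pca
    eig = pd.DataFrame(
        {
            "axis": [f"PC{k + 1}" for k in range(len(pca.eigenvalues))],
            "eigenvalue": pca.eigenvalues,
            "explained_fraction": pca.explained_fraction,
            "broken_stick": pca.broken_stick,
        }
    )
    eig.to_csv(outdir / "pca_eigenvalues.tsv", sep="\t", index=False)
    pca.species_scores.to_csv(outdir / "pca_species_scores.tsv", sep="\t")
    pd.DataFrame(pca.eigenvectors, index=pca.trait_names,
                 columns=[f"PC{k + 1}" for k in range(pca.eigenvectors.shape[1])]
                 ).to_csv(outdir / "pca_loadings.tsv", sep="\t")
    result.correlations.to_csv(outdir / "fa_pc_correlations.tsv", sep="\t", index=False)
    (outdir / "run_log.txt").write_text("\n".join(result.log) + "\n")
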