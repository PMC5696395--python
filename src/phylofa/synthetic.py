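"""Synthetic trees and compositional FA tables with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
pure-birth (Yule) ultrametric phylogeny; a latent logit-scale abundance per
species per FA in which some FAs evolve by Brownian motion along the tree
(phylogenetically conserved, λ_true = 1) and others are drawn independently
per species (labile, λ_true = 0); within-species replicate noise on the
latent scale; and a softmax-style closure mapping latent values to
proportions summing to 100%. Per-FA λ_true and the latent species means are
returned alongside so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylogeny, parse_newick, phylo_covariance, lambda_transform

__all__ = ["SyntheticSpec", "GroundTruth", "yule_tree", "simulate_lambda_traits", "synthetic_fa_table"]

# Default FA panel at the study's scale (~20 FAs): conserved physiological /
# structural FAs vs labile diet-biomarker FAs.
_CONSERVED_DEFAULT = (
    "14:0", "15:0", "16:0", "18:0", "20:1w9", "20:2w6,9", "20:3w6", "20:4w6", "20:5w3", "22:2",
)
_LABILE_DEFAULT = (
    "a15:0", "i15:0", "i16:0", "16:1w5", "16:1w7", "i17:0", "cy17:0", "18:1w7", "cy19:0",
    "18:1w9", "18:2w6,9",
)


@dataclass
class SyntheticSpec:
    """Study-shaped generator settings.

    Defaults mirror the scale of the field study the analysis is designed
    for: tens of species, ~20 FAs, a few replicate measurements per species,
    Brownian rate and replicate noise on the latent logit scale.
    """

    n_species: int = 40
    birth_rate: float = 1.0
    conserved_fas: tuple[str, ...] = _CONSERVED_DEFAULT
    labile_fas: tuple[str, ...] = _LABILE_DEFAULT
    bm_rate: float = 1.0
    replicate_noise_sd: float = 0.5
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.conserved_fas) & set(self.labile_fas):
            raise ValueError("conserved and labile FA sets must be disjoint")
        if self.bm_rate <= 0 or self.replicate_noise_sd < 0 or self.birth_rate <= 0:
            raise ValueError("rates must be positive and noise sd nonnegative")

    @property
    def fa_names(self) -> tuple[str, ...]:
        return self.conserved_fas + self.labile_fas


@dataclass
class GroundTruth:
    """What the generator actually did: per-FA λ_true and latent species means."""

    lambda_true: pd.Series
    latent_means: pd.DataFrame
    spec: SyntheticSpec = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        out = self.latent_means.copy()
        out.loc["lambda_true"] = self.lambda_true
        return out


def yule_tree(n_species: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0) -> Phylogeny:
    """Simulate an ultrametric pure-birth tree with ``n_species`` tips.

    Starting from two lineages at the root, waiting times between speciation
    events are Exp(k·birth_rate) while k lineages are extant; a final
    Exp(n·birth_rate) stretch follows the last split so no terminal branch
    has zero length. Tip labels are t01, t02, … in the order lineages were
    born. Fully reproducible under an integer seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    class _N:
        __slots__ = ("children", "length", "label")

        def __init__(self):
            self.children, self.length, self.label = [], 0.0, None

    left, right = _N(), _N()
    active = [left, right]
    for k in range(2, n_species):
        dt = rng.exponential(1.0 / (birth_rate * k))
        for a in active:
            a.length += dt
        idx = int(rng.integers(len(active)))
        parent = active[idx]
        c1, c2 = _N(), _N()
        parent.children = [c1, c2]
        active[idx:idx + 1] = [c1, c2]
    dt = rng.exponential(1.0 / (birth_rate * n_species))
    for a in active:
        a.length += dt
    width = len(str(n_species))
    for i, tip in enumerate(active, start=1):
        tip.label = f"t{i:0{width}d}"

    def nwk(node: _N) -> str:
        if not node.children:
            return f"{node.label}:{node.length!r}"
        inner = ",".join(nwk(c) for c in node.children)
        return f"({inner}):{node.length!r}"

    text = f"({nwk(left)},{nwk(right)});"
    return parse_newick(text)


def simulate_lambda_traits(
    tree: Phylogeny,
    lam_true: float,
    sigma2: float = 1.0,
    n_traits: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw traits from N(0, σ²·C(λ)) with C(λ) the λ-transformed tree covariance.

    λ = 1 reproduces Brownian motion; λ = 0 gives independent normals with
    the root-to-tip variances. Rows follow the canonical (sorted) tip order.
    """
    if not 0 <= lam_true:
        raise ValueError("lam_true must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = lambda_transform(phylo_covariance(tree), lam_true)
    w, U = np.linalg.eigh(sigma2 * cov.C)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    return L @ rng.standard_normal((cov.n, n_traits))


def synthetic_fa_table(spec: SyntheticSpec, tree: Phylogeny | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a replicate-level compositional FA table with known ground truth.

    Latent logit abundances per species: a per-FA baseline draw plus a BM
    deviation on the tree for conserved FAs or an i.i.d. normal deviation for
    labile FAs. Replicates add N(0, replicate_noise_sd²) on the latent scale.
    Rows are closed to proportions summing to 100% by exponentiation and
    renormalization, so the Brownian assumption lives on the (logit-like)
    latent scale the analysis actually tests.
    """
    if spec.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(spec.seed)
    if tree is None:
        tree = yule_tree(spec.n_species, spec.birth_rate, seed=rng)
    species = tree.tip_names
    n = len(species)
    fas = list(spec.fa_names)
    cov = phylo_covariance(tree)
    # tree height normalized out of the rate so bm_rate is per unit height
    scale = spec.bm_rate / np.mean(np.diag(cov.C))
    baselines = rng.normal(0.0, 1.0, size=len(fas))
    latent = np.empty((n, len(fas)))
    lam_true = {}
    for j, fa in enumerate(fas):
        conserved = fa in spec.conserved_fas
        lam_true[fa] = 1.0 if conserved else 0.0
        dev = simulate_lambda_traits(tree, lam_true[fa], sigma2=scale, n_traits=1, seed=rng)[:, 0]
        latent[:, j] = baselines[j] + dev
    rows = []
    for i, sp in enumerate(species):
        for r in range(spec.n_replicates):
            noise = rng.normal(0.0, spec.replicate_noise_sd, size=len(fas))
            expo = np.exp(latent[i] + noise)
            props = 100.0 * expo / expo.sum()
            rows.append(
                {"sample_id": f"{sp}_r{r + 1}", "species": sp, "site": "synthetic", "habitat": "synthetic",
                 **dict(zip(fas, props))}
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        lambda_true=pd.Series(lam_true),
        latent_means=pd.DataFrame(latent, index=species, columns=fas),
        spec=spec,
    )
    return table, truth
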