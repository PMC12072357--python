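"""Paired bulk/single-cell synthetic data with pathway-driven response.

The generator emulates the statistical structure the real task presents:
negative-binomial counts; single-cell libraries far shallower and
sparser than bulk (multiplicative library-size gap plus zero-inflation
thinning); a systematic bulk-vs-sc shift in per-gene means; and a drug
response signal that lives in the activity of a few *causal* pathways.

Sensitive samples carry ``effect_size`` extra activity on the causal
pathways, which propagates to member-gene means; the bulk dose-response
AUC is a noisy decreasing function of causal activity, so lower AUC
means more sensitive and the extreme-value labeler recovers the ground
truth at the tails.  At ``effect_size = 0`` the AUC is pure noise and
every downstream recovery collapses to chance, which the tests use as a
negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .labeling import DrugResponseTable
from .pathways import GeneSet, GeneSetCollection


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 1000
    n_pathways: int = 50
    genes_per_pathway: tuple[int, int] = (10, 20)
    n_bulk: int = 400
    n_sc: int = 1000
    causal_pathways: tuple[int, ...] = (0, 1, 2)
    effect_size: float = 3.0
    sc_dropout_rate: float = 0.3
    library_size_bulk: float = 5e4
    library_size_sc: float = 5e3
    dispersion: float = 0.1
    domain_shift_scale: float = 0.5
    auc_noise_sd: float = 0.3
    loading_range: tuple[float, float] = (0.3, 0.7)
    activity_sd: float = 1.0
    sensitive_fraction: float = 0.5

    def __post_init__(self):
        if not set(self.causal_pathways) <= set(range(self.n_pathways)):
            raise ValueError("causal_pathways must index defined pathways")
        if not (0 <= self.sc_dropout_rate < 1):
            raise ValueError("sc_dropout_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.effect_size > 0 and not self.causal_pathways:
            raise ValueError("effect_size > 0 requires at least one causal pathway")


@dataclass
class SyntheticDataset:
    bulk: ExpressionMatrix
    sc: ExpressionMatrix
    response: DrugResponseTable
    gene_sets: GeneSetCollection
    bulk_labels: dict[str, int]  # ground-truth sensitive flags
    sc_labels: dict[str, int]
    causal_pathway_names: list[str]
    bulk_causal_activity: np.ndarray = field(repr=False, default=None)
    bulk_activity: np.ndarray = field(repr=False, default=None)  # samples x pathways
    sc_activity: np.ndarray = field(repr=False, default=None)
    config: SyntheticConfig | None = None

    def write(self, outdir: str | Path) -> None:
        """Dump every artifact in the formats the loaders read."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.bulk.to_csv(outdir / "bulk.csv")
        self.sc.to_csv(outdir / "sc.csv")
        df = self.response.entries.copy()
        df.insert(0, "drug", self.response.drug_name)
        df.to_csv(outdir / "response.csv", index=False)
        self.gene_sets.to_gmt(outdir / "pathways.gmt")
        truth = pd.DataFrame(
            {
                "sample_id": list(self.bulk_labels) + list(self.sc_labels),
                "domain": ["bulk"] * len(self.bulk_labels) + ["sc"] * len(self.sc_labels),
                "label": list(self.bulk_labels.values()) + list(self.sc_labels.values()),
            }
        )
        truth.to_csv(outdir / "truth.csv", index=False)
        (outdir / "causal_pathways.txt").write_text(
            "\n".join(self.causal_pathway_names) + "\n"
        )


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(np.float64)


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{j:04d}" for j in range(cfg.n_genes)]
    pathway_names = [f"PW{p:03d}" for p in range(cfg.n_pathways)]

    # Disjoint gene-to-pathway assignment: each pathway draws its genes
    # from a shuffled pool without replacement, so membership (and hence
    # attribution ground truth) is unambiguous.  Genes left over after
    # all pathways are filled belong to no pathway.
    lo, hi = cfg.genes_per_pathway
    pool = rng.permutation(cfg.n_genes)
    members: list[np.ndarray] = []
    loadings = np.zeros((cfg.n_pathways, cfg.n_genes))
    start = 0
    for p in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if start + size > cfg.n_genes:
            raise ValueError(
                "n_genes too small for a disjoint assignment of "
                f"{cfg.n_pathways} pathways of up to {hi} genes"
            )
        idx = pool[start : start + size]
        start += size
        members.append(np.sort(idx))
        loadings[p, idx] = rng.uniform(*cfg.loading_range, size=size)
    gene_sets = GeneSetCollection(
        sets=[
            GeneSet(name=pathway_names[p], description="synthetic pathway",
                    genes=[genes[j] for j in members[p]])
            for p in range(cfg.n_pathways)
        ]
    )

    log_baseline = rng.normal(1.0, 1.0, size=cfg.n_genes)
    causal = np.array(cfg.causal_pathways, dtype=int)

    def sample_domain(n, library_size, shift, dropout, id_fmt, loading_scale=None):
        s = (rng.random(n) < cfg.sensitive_fraction).astype(int)
        activity = rng.normal(0.0, cfg.activity_sd, size=(n, cfg.n_pathways))
        if causal.size:
            activity[:, causal] += cfg.effect_size * s[:, None]
        eff_loadings = loadings if loading_scale is None else loadings * loading_scale
        log_mu = log_baseline[None, :] + activity @ eff_loadings + shift[None, :]
        rel = np.exp(log_mu)
        rel /= rel.sum(axis=1, keepdims=True)
        mean_counts = rel * library_size
        counts = _nb_counts(rng, mean_counts, cfg.dispersion)
        if dropout > 0:
            # Expression-dependent zero inflation: p_drop(gene) decays
            # exponentially with its mean count (the classic detection-
            # efficiency pattern), with the decay rate solved so the
            # overall zeroed fraction equals `dropout`.  This is the part
            # of the bulk/sc domain shift that per-gene standardization
            # cannot remove.
            gene_mean = mean_counts.mean(axis=0)
            lam_lo, lam_hi = 0.0, 100.0
            for _ in range(60):
                lam = 0.5 * (lam_lo + lam_hi)
                if np.exp(-lam * gene_mean).mean() > dropout:
                    lam_lo = lam
                else:
                    lam_hi = lam
            p_drop = np.exp(-lam * gene_mean)
            counts *= rng.random(counts.shape) >= p_drop[None, :]
        ids = [id_fmt.format(i) for i in range(n)]
        return s, activity, counts, ids

    no_shift = np.zeros(cfg.n_genes)
    s_b, act_b, counts_b, ids_b = sample_domain(
        cfg.n_bulk, cfg.library_size_bulk, no_shift, 0.0, "line{:04d}"
    )
    # Platform shift for the single-cell domain: a per-gene baseline
    # offset plus a per-gene random rescaling of the pathway loadings
    # (gene-specific attenuation/amplification of the biological signal,
    # as capture-efficiency and length biases produce in practice).  The
    # loading rescaling is the part per-gene standardization cannot
    # remove.
    sc_shift = rng.normal(0.0, cfg.domain_shift_scale, size=cfg.n_genes)
    sc_loading_scale = np.exp(
        rng.normal(0.0, cfg.domain_shift_scale, size=cfg.n_genes)
    )[None, :]
    s_c, act_c, counts_c, ids_c = sample_domain(
        cfg.n_sc, cfg.library_size_sc, sc_shift, cfg.sc_dropout_rate, "cell{:05d}",
        loading_scale=sc_loading_scale,
    )

    # AUC: noisy decreasing function of causal activity; at effect_size 0
    # it is independent of expression and labels are coin flips.
    cbar = act_b[:, causal].mean(axis=1) if causal.size else np.zeros(cfg.n_bulk)
    noise = rng.normal(0.0, cfg.auc_noise_sd, size=cfg.n_bulk)
    auc = 1.0 / (1.0 + np.exp(cfg.effect_size * cbar - noise))
    response = DrugResponseTable(
        drug_name="synthetic_drug",
        entries=pd.DataFrame({"cell_line_id": ids_b, "auc": auc}),
    )

    return SyntheticDataset(
        bulk=ExpressionMatrix(counts_b, genes, ids_b, "bulk"),
        sc=ExpressionMatrix(counts_c, genes, ids_c, "sc"),
        response=response,
        gene_sets=gene_sets,
        bulk_labels=dict(zip(ids_b, map(int, s_b))),
        sc_labels=dict(zip(ids_c, map(int, s_c))),
        causal_pathway_names=[pathway_names[p] for p in causal],
        bulk_causal_activity=cbar,
        bulk_activity=act_b,
        sc_activity=act_c,
        config=cfg,
    )
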