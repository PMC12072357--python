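"""Two-stage training and bulk-to-single-cell transfer inference.

Stage 1 pretrains the autoencoder jointly on bulk and single-cell
matrices (one batch from each domain per step), minimizing the
mode-dependent objective.  Stage 2 fine-tunes the
shared encoder together with the sigmoid classifier on the extreme-
value-labeled bulk lines while a pathway-reconstruction anchor keeps
the latent dimensions tied to their pathways, then polishes the
classifier on frozen embeddings.  The trained classifier is applied
directly to single-cell embeddings: the transfer step.

Ablation modes: ``base_ae`` (single encoder, plain reconstruction),
``share_ae`` (private+shared encoders with the orthogonality term), and
``share_ae_pathways`` (additionally the pathway-masked sparse decoder).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .expression import ExpressionMatrix
from .labeling import BinaryLabels
from .metrics import confusion, scores
from ._autodiff import Tensor
from .model import (
    Adam,
    ArchitectureConfig,
    ModelParameters,
    bce_loss,
    classify,
    encode,
    sparse_decode,
    total_losses,
)
from .pathways import PathwayMask


@dataclass
class TrainConfig:
    seed: int = 0
    pretrain_epochs: int = 30
    classifier_epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    val_fraction: float = 0.1
    n_repeats: int = 5
    freeze_encoder_in_stage2: bool = False
    early_stop_patience: int = 30
    stage2_anchor_weight: float = 0.3
    mode: str = "share_ae_pathways"

    def __post_init__(self):
        if not (0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in (0, 0.5)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be adam or sgd")


@dataclass
class TrainingLog:
    records: list[dict] = field(default_factory=list)
    seed: int = 0
    wall_clock: float = 0.0

    def append(self, **kw) -> None:
        self.records.append(kw)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


class _SGD:
    def __init__(self, params, lr):
        self.params, self.lr = params, lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.value -= self.lr * p.grad


def _make_optimizer(params, cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return Adam(params, lr=cfg.learning_rate)
    return _SGD(params, lr=cfg.learning_rate)


def _check_preprocessed(x: ExpressionMatrix) -> None:
    if not x.stages:
        raise ValueError(f"{x.domain} matrix is raw; run preprocess() first")


def pretrain(
    bulk: ExpressionMatrix,
    sc: ExpressionMatrix,
    mask: PathwayMask | None,
    arch: ArchitectureConfig,
    cfg: TrainConfig,
) -> tuple[ModelParameters, TrainingLog]:
    """Stage-1 joint autoencoder pretraining.

    Returns the parameters at the epoch with the lowest validation
    L_train, plus the per-epoch log.  Fully reproducible given
    ``cfg.seed``.
    """
    t0 = time.time()
    _check_preprocessed(bulk)
    _check_preprocessed(sc)
    if bulk.gene_names != sc.gene_names:
        raise ValueError("bulk and sc gene spaces are not aligned")
    arch.mode = cfg.mode
    if cfg.mode == "share_ae_pathways":
        if mask is None:
            raise ValueError("share_ae_pathways mode requires a pathway mask")
        if mask.gene_names != bulk.gene_names:
            raise ValueError("mask gene order does not match the expression matrices")
        if arch.latent_dim_shared != mask.n_rows:
            raise ValueError(
                f"latent_dim_shared={arch.latent_dim_shared} must equal mask row "
                f"count {mask.n_rows}"
            )
        mask_arr, row_names = mask.matrix.astype(np.float64), mask.row_names
    else:
        mask_arr, row_names = None, []

    rng = np.random.default_rng(cfg.seed)
    params = ModelParameters.init(arch, rng, mask=mask_arr, mask_row_names=row_names)
    ae_params = params.autoencoder_parameters()
    opt = _make_optimizer(ae_params, cfg)

    def split(n):
        idx = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        return idx[n_val:], idx[:n_val]

    tr_b, va_b = split(bulk.n_samples)
    tr_s, va_s = split(sc.n_samples)
    xb, xs = bulk.values, sc.values
    if cfg.mode == "base_ae":
        # no transfer learning: the naive autoencoder never sees the
        # single-cell data, it trains on bulk alone
        tr_s, va_s, xs = tr_b, va_b, xb
    steps = int(np.ceil(max(len(tr_b), len(tr_s)) / cfg.batch_size))

    log = TrainingLog(seed=cfg.seed)
    best_val, best_state, best_epoch = np.inf, None, -1
    for epoch in range(cfg.pretrain_epochs):
        pb = tr_b[rng.permutation(len(tr_b))]
        ps = tr_s[rng.permutation(len(tr_s))]
        for step in range(steps):
            bb = pb[np.arange(step * cfg.batch_size, (step + 1) * cfg.batch_size) % len(pb)]
            bs = ps[np.arange(step * cfg.batch_size, (step + 1) * cfg.batch_size) % len(ps)]
            losses = total_losses(xb[bb], xs[bs], params, train=True, rng=rng)
            if not np.isfinite(losses["train"].value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}; "
                    f"best checkpoint so far was epoch {best_epoch}"
                )
            opt.zero_grad()
            losses["train"].backward()
            opt.step()
            params.apply_mask()
        val = total_losses(xb[va_b], xs[va_s], params)
        trn = total_losses(xb[tr_b], xs[tr_s], params)
        log.append(
            stage="pretrain",
            epoch=epoch,
            L_recon=float(trn["recon"].value),
            L_diff=float(trn["diff"].value),
            L_sparse=float(trn["sparse"].value),
            L_train=float(trn["train"].value),
            val_L_train=float(val["train"].value),
        )
        if val["train"].value < best_val:
            best_val = float(val["train"].value)
            best_epoch = epoch
            best_state = [p.value.copy() for p in ae_params]
    if best_state is not None:
        for p, v in zip(ae_params, best_state):
            p.value = v
    params.apply_mask()
    log.wall_clock = time.time() - t0
    return params, log


def _fit_classifier_phase(
    params: ModelParameters,
    x: np.ndarray,
    y: np.ndarray,
    idx_tr: np.ndarray,
    idx_va: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
    log: TrainingLog,
    stage: str,
    fine_tune: bool,
    sc_values: np.ndarray | None,
) -> None:
    """One early-stopped training phase; mutates `params` in place.

    With ``fine_tune`` the shared encoder trains alongside the
    classifier and, when a pathway mask is present, the objective keeps
    the sparse-reconstruction anchor on both the bulk batch and (if
    given) a random batch of unlabeled single cells, so the label signal
    is forced through latent dimensions that still reconstruct their own
    pathway's genes.  The sparse decoder itself stays frozen here: were
    its rows trainable, the model could zero them out and park label
    signal in arbitrary dimensions at no reconstruction cost.
    """
    anchored = fine_tune and params.sparse_W is not None
    off = params.arch.sparse_target_offset
    w = cfg.stage2_anchor_weight
    if not fine_tune:
        z_all = encode(x, params, "bulk").shared  # fixed features
    opt_params = params.classifier_parameters()
    if fine_tune:
        opt_params = opt_params + [
            t for lin in params.shared_encoder for t in (lin.W, lin.b)
        ]
    opt = _make_optimizer(opt_params, cfg)

    best_key, best_state, patience = None, None, 0
    for epoch in range(cfg.classifier_epochs):
        perm = idx_tr[rng.permutation(len(idx_tr))]
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            if fine_tune:
                z = encode(x[batch], params, "bulk", train=True, rng=rng).z_shared
            else:
                z = z_all[batch]
            p = classify(z, params, train=True, rng=rng)
            loss = bce_loss(y[batch], p)
            if anchored:
                target = Tensor(x[batch] + off)
                loss = loss + w * (target - sparse_decode(z, params)).square().mean()
                if sc_values is not None:
                    xs = sc_values[rng.choice(sc_values.shape[0], cfg.batch_size)]
                    zs = encode(xs, params, "sc", train=True, rng=rng).z_shared
                    loss = loss + w * (
                        Tensor(xs + off) - sparse_decode(zs, params)
                    ).square().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            params.apply_mask()

        def _eval(sel):
            z = encode(x[sel], params, "bulk").shared if fine_tune else z_all[sel]
            p = classify(z, params).value.reshape(-1)
            bce = float(bce_loss(y[sel], p).value)
            acc, _, _, f1 = scores(confusion(y[sel].astype(int), (p >= 0.5).astype(int)))
            return bce, acc, f1

        tr_bce, tr_acc, tr_f1 = _eval(idx_tr)
        va_bce, va_acc, va_f1 = _eval(idx_va)
        log.append(
            stage=stage, epoch=epoch,
            train_bce=tr_bce, train_acc=tr_acc, train_f1=tr_f1,
            val_bce=va_bce, val_acc=va_acc, val_f1=va_f1,
        )
        # lowest validation BCE wins; F1 breaks ties.  BCE is a proper
        # scoring rule: unlike F1 it does not reward positive-heavy
        # classifiers when the labels carry no signal.
        key = (va_bce, -va_f1)
        if best_key is None or key < best_key:
            best_key = key
            best_state = [p_.value.copy() for p_ in opt_params]
            patience = 0
        else:
            patience += 1
            if patience >= cfg.early_stop_patience:
                break
    if best_state is not None:
        for p_, v in zip(opt_params, best_state):
            p_.value = v


def train_classifier(
    params: ModelParameters,
    bulk: ExpressionMatrix,
    labels: BinaryLabels,
    cfg: TrainConfig,
    sc: ExpressionMatrix | None = None,
) -> tuple[ModelParameters, TrainingLog]:
    """Stage-2 classifier training on labeled bulk embeddings.

    With ``freeze_encoder_in_stage2`` the shared encoder is untouched and
    the classifier trains on fixed embeddings.  Otherwise training runs
    in two phases: (1) pathway-anchored fine-tuning of encoder plus
    classifier (see ``_fit_classifier_phase``; pass ``sc`` to extend the
    unsupervised anchor to the target domain), then (2) a classifier-only
    polish on the now-frozen embeddings.  Model selection per phase:
    epoch with the lowest validation BCE, ties broken by best F1.
    """
    t0 = time.time()
    _check_preprocessed(bulk)
    ids = [s for s in bulk.sample_ids if s in labels.labels]
    missing = set(labels.labels) - set(bulk.sample_ids)
    if missing:
        raise ValueError(f"labeled ids absent from bulk matrix: {sorted(missing)[:5]}")
    y = np.array([labels.labels[s] for s in ids], dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    row = {s: i for i, s in enumerate(bulk.sample_ids)}
    x = bulk.values[[row[s] for s in ids]]

    idx_tr, idx_va = train_test_split(
        np.arange(len(ids)),
        test_size=cfg.val_fraction,
        stratify=y,
        random_state=cfg.seed % (2**32),
    )
    log = TrainingLog(seed=cfg.seed)
    sc_values = None
    if sc is not None:
        _check_preprocessed(sc)
        sc_values = sc.values
    if cfg.freeze_encoder_in_stage2:
        rng = np.random.default_rng(cfg.seed + 1)
        _fit_classifier_phase(
            params, x, y, idx_tr, idx_va, cfg, rng, log, "classifier",
            fine_tune=False, sc_values=None,
        )
    else:
        rng = np.random.default_rng(cfg.seed + 1)
        _fit_classifier_phase(
            params, x, y, idx_tr, idx_va, cfg, rng, log, "classifier_finetune",
            fine_tune=True, sc_values=sc_values,
        )
        rng = np.random.default_rng(cfg.seed + 2)
        _fit_classifier_phase(
            params, x, y, idx_tr, idx_va, cfg, rng, log, "classifier",
            fine_tune=False, sc_values=None,
        )
    log.wall_clock = time.time() - t0
    return params, log


def predict_sc(
    params: ModelParameters, sc: ExpressionMatrix, threshold: float = 0.5
) -> pd.DataFrame:
    """Transfer the bulk-trained classifier to single cells.

    Returns a DataFrame with per-cell probability of sensitivity and the
    binary call at ``threshold``.
    """
    _check_preprocessed(sc)
    if sc.n_genes != params.arch.n_genes:
        raise ValueError(
            f"sc matrix has {sc.n_genes} genes, model expects {params.arch.n_genes}"
        )
    z = encode(sc.values, params, "sc").shared
    prob = classify(z, params).value.reshape(-1)
    return pd.DataFrame(
        {
            "cell_id": sc.sample_ids,
            "probability": prob,
            "call": (prob >= threshold).astype(int),
        }
    )
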