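"""Model architecture and losses.

The model is a shared/private autoencoder bridging bulk and single-cell
expression:

* one *private* two-layer encoder per domain captures platform-specific
  variation;
* one *shared* two-layer encoder, applied with identical parameters to
  both domains, projects them into a common latent space;
* a dense two-layer decoder reconstructs expression from the
  concatenated private+shared embedding;
* a single-layer *sparse decoder* reconstructs expression from the
  shared embedding alone through a weight matrix elementwise-masked by
  the binary pathway-gene matrix, which ties each shared-latent
  dimension to one pathway (plus a few unconstrained free rows);
* a three-layer sigmoid classifier maps shared embeddings to the
  probability of drug sensitivity.

Losses:  L_recon (MSE, both domains) + r1 * L_diff (squared Frobenius
norm of the private/shared cross-correlation, pushing the two
embeddings orthogonal) forms L_AE; adding r2 * L_sparse (MSE of the
masked reconstruction) gives the pretraining objective L_train.  The
classifier trains with binary cross-entropy.

Everything runs on the in-package autodiff engine; all forward
functions accept NumPy arrays and return `Tensor`s whose ``.value`` is
the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat

MODES = ("base_ae", "share_ae", "share_ae_pathways")


@dataclass
class ArchitectureConfig:
    n_genes: int
    latent_dim_shared: int
    latent_dim_private: int | None = None  # defaults to latent_dim_shared
    hidden_dim: int = 256
    dropout: float = 0.2
    r1: float = 0.1
    r2: float = 0.1
    classifier_hidden: tuple[int, int] = (128, 64)
    mode: str = "share_ae_pathways"
    # Constant added to the expression matrix when it is the sparse
    # decoder's target.  Standardized expression is zero-centered, which
    # a ReLU output cannot represent (training collapses to the dead
    # all-zero solution and the pathway constraint stops shaping the
    # encoder); shifting the target, with the sparse bias initialized at
    # the shift, keeps the head live.
    sparse_target_offset: float = 2.0

    def __post_init__(self):
        if self.latent_dim_private is None:
            self.latent_dim_private = self.latent_dim_shared
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("r1, r2 must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class Linear:
    W: Tensor
    b: Tensor

    @classmethod
    def init(cls, n_in: int, n_out: int, rng: np.random.Generator) -> "Linear":
        scale = np.sqrt(2.0 / n_in)  # He init; ReLU follows most layers
        return cls(
            W=Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True),
            b=Tensor(np.zeros(n_out), requires_grad=True),
        )

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


@dataclass
class LatentEmbedding:
    """Private and shared latent coordinates for one encoded batch."""

    z_private: Tensor | None
    z_shared: Tensor
    domain: str

    @property
    def shared(self) -> np.ndarray:
        return self.z_shared.value

    @property
    def private(self) -> np.ndarray | None:
        return None if self.z_private is None else self.z_private.value


def _two_layer(x: Tensor, l1: Linear, l2: Linear, dropout_mask=None) -> Tensor:
    h = l1(x).relu()
    if dropout_mask is not None:
        h = h * dropout_mask
    return l2(h)


def _dropout_mask(shape, rate: float, rng: np.random.Generator | None) -> Tensor | None:
    """Inverted-dropout mask, or None when inactive."""
    if rng is None or rate <= 0:
        return None
    keep = rng.random(shape) >= rate
    return Tensor(keep / (1.0 - rate))


@dataclass
class ModelParameters:
    arch: ArchitectureConfig
    shared_encoder: tuple[Linear, Linear]
    private_encoder_bulk: tuple[Linear, Linear] | None
    private_encoder_sc: tuple[Linear, Linear] | None
    decoder: tuple[Linear, Linear]
    sparse_W: Tensor | None
    sparse_b: Tensor | None
    mask: np.ndarray | None
    classifier: tuple[Linear, Linear, Linear]
    mask_row_names: list[str] = field(default_factory=list)

    @classmethod
    def init(
        cls,
        arch: ArchitectureConfig,
        rng: np.random.Generator,
        mask: np.ndarray | None = None,
        mask_row_names: list[str] | None = None,
    ) -> "ModelParameters":
        g, h = arch.n_genes, arch.hidden_dim
        ds, dp = arch.latent_dim_shared, arch.latent_dim_private
        with_private = arch.mode != "base_ae"
        with_mask = arch.mode == "share_ae_pathways"
        if with_mask:
            if mask is None:
                raise ValueError("mode share_ae_pathways requires a pathway mask")
            mask = np.asarray(mask, dtype=np.float64)
            if mask.shape != (ds, g):
                raise ValueError(
                    f"mask shape {mask.shape} != (latent_dim_shared={ds}, n_genes={g})"
                )
        shared = (Linear.init(g, h, rng), Linear.init(h, ds, rng))
        priv_b = (Linear.init(g, h, rng), Linear.init(h, dp, rng)) if with_private else None
        priv_s = (Linear.init(g, h, rng), Linear.init(h, dp, rng)) if with_private else None
        dec_in = ds + (dp if with_private else 0)
        decoder = (Linear.init(dec_in, h, rng), Linear.init(h, g, rng))
        if with_mask:
            # Constant positive init on allowed positions (not random):
            # the early gradient through row d then pulls latent dim d
            # toward the mean expression of its own pathway's genes,
            # seeding the dim-to-pathway correspondence the mask is
            # meant to enforce.
            sparse_W = Tensor(mask.copy(), requires_grad=True)
            sparse_b = Tensor(
                np.full(g, arch.sparse_target_offset), requires_grad=True
            )
        else:
            sparse_W = sparse_b = None
        c1, c2 = arch.classifier_hidden
        classifier = (
            Linear.init(ds, c1, rng),
            Linear.init(c1, c2, rng),
            Linear.init(c2, 1, rng),
        )
        return cls(
            arch=arch,
            shared_encoder=shared,
            private_encoder_bulk=priv_b,
            private_encoder_sc=priv_s,
            decoder=decoder,
            sparse_W=sparse_W,
            sparse_b=sparse_b,
            mask=mask,
            classifier=classifier,
            mask_row_names=list(mask_row_names or []),
        )

    # -- parameter bookkeeping ---------------------------------------------

    def autoencoder_parameters(self) -> list[Tensor]:
        groups = [self.shared_encoder, self.decoder]
        if self.private_encoder_bulk is not None:
            groups += [self.private_encoder_bulk, self.private_encoder_sc]
        params = [t for grp in groups for lin in grp for t in (lin.W, lin.b)]
        if self.sparse_W is not None:
            params += [self.sparse_W, self.sparse_b]
        return params

    def classifier_parameters(self) -> list[Tensor]:
        return [t for lin in self.classifier for t in (lin.W, lin.b)]

    def all_parameters(self) -> list[Tensor]:
        return self.autoencoder_parameters() + self.classifier_parameters()

    def apply_mask(self) -> None:
        """Zero the sparse-decoder weight at mask-zero positions (exactly)."""
        if self.sparse_W is not None:
            self.sparse_W.value *= self.mask

    # -- serialization -------------------------------------------------------

    def _named(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        groups = {
            "shared": self.shared_encoder,
            "priv_bulk": self.private_encoder_bulk,
            "priv_sc": self.private_encoder_sc,
            "decoder": self.decoder,
            "classifier": self.classifier,
        }
        for name, grp in groups.items():
            if grp is None:
                continue
            for i, lin in enumerate(grp):
                out[f"{name}.{i}.W"] = lin.W
                out[f"{name}.{i}.b"] = lin.b
        if self.sparse_W is not None:
            out["sparse.W"] = self.sparse_W
            out["sparse.b"] = self.sparse_b
        return out

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        arrays = {k: t.value for k, t in self._named().items()}
        if self.mask is not None:
            arrays["mask"] = self.mask
        np.savez(stem.with_suffix(".npz"), **arrays)
        manifest = {"arch": asdict(self.arch), "mask_row_names": self.mask_row_names}
        stem.with_suffix(".manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, stem: str | Path) -> "ModelParameters":
        stem = Path(stem)
        manifest = json.loads(stem.with_suffix(".manifest.json").read_text())
        arch_d = manifest["arch"]
        arch_d["classifier_hidden"] = tuple(arch_d["classifier_hidden"])
        arch = ArchitectureConfig(**arch_d)
        data = np.load(stem.with_suffix(".npz"))
        params = cls.init(
            arch,
            np.random.default_rng(0),
            mask=data["mask"] if "mask" in data else None,
            mask_row_names=manifest["mask_row_names"],
        )
        for k, t in params._named().items():
            t.value = np.asarray(data[k], dtype=np.float64)
        return params


# -- forward ops -------------------------------------------------------------


def encode(
    x,
    params: ModelParameters,
    domain: str,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> LatentEmbedding:
    """Encode a batch through the domain's private and the shared encoder.

    Dropout (rate ``arch.dropout``) is applied after the first ReLU only
    when ``train`` is set and an rng is given.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.value.shape[1] != params.arch.n_genes:
        raise ValueError(
            f"batch has {x.value.shape[1]} genes, model expects {params.arch.n_genes}"
        )
    drop = params.arch.dropout if train else 0.0
    n = x.value.shape[0]
    h = params.arch.hidden_dim
    z_s = _two_layer(x, *params.shared_encoder, _dropout_mask((n, h), drop, rng))
    if params.private_encoder_bulk is None:
        return LatentEmbedding(z_private=None, z_shared=z_s, domain=domain)
    enc = params.private_encoder_bulk if domain == "bulk" else params.private_encoder_sc
    z_p = _two_layer(x, *enc, _dropout_mask((n, h), drop, rng))
    return LatentEmbedding(z_private=z_p, z_shared=z_s, domain=domain)


def decode(z: LatentEmbedding, params: ModelParameters) -> Tensor:
    """Reconstruct expression from the concatenated private+shared latent."""
    if z.z_private is not None:
        latent = concat([z.z_private, z.z_shared], axis=1)
    else:
        latent = z.z_shared
    return _two_layer(latent, *params.decoder)


def sparse_decode(z_shared, params: ModelParameters) -> Tensor:
    """Masked single-layer reconstruction from the shared latent.

    Gene j receives contributions only from latent rows whose mask entry
    is 1 (free rows contribute everywhere)."""
    if params.sparse_W is None:
        raise ValueError("model was built without a sparse decoder")
    z = z_shared if isinstance(z_shared, Tensor) else Tensor(z_shared)
    if z.value.shape[1] != params.mask.shape[0]:
        raise ValueError(
            f"latent width {z.value.shape[1]} != mask row count {params.mask.shape[0]}"
        )
    w = params.sparse_W * Tensor(params.mask)
    return (z @ w + params.sparse_b).relu()


def classify(
    z_shared,
    params: ModelParameters,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Three-layer sigmoid classifier: P(sensitive) per sample."""
    z = z_shared if isinstance(z_shared, Tensor) else Tensor(z_shared)
    l1, l2, l3 = params.classifier
    drop = params.arch.dropout if train else 0.0
    n = z.value.shape[0]
    h1 = l1(z).relu()
    m1 = _dropout_mask(h1.value.shape, drop, rng)
    if m1 is not None:
        h1 = h1 * m1
    h2 = l2(h1).relu()
    m2 = _dropout_mask(h2.value.shape, drop, rng)
    if m2 is not None:
        h2 = h2 * m2
    return l3(h2).sigmoid()


# -- losses ------------------------------------------------------------------


def loss_recon(x_sc, x_bulk, xhat_sc: Tensor, xhat_bulk: Tensor) -> Tensor:
    """Sum over domains of the mean squared reconstruction error."""
    x_sc = x_sc if isinstance(x_sc, Tensor) else Tensor(x_sc)
    x_bulk = x_bulk if isinstance(x_bulk, Tensor) else Tensor(x_bulk)
    for x, xh in ((x_sc, xhat_sc), (x_bulk, xhat_bulk)):
        if x.value.shape != xh.value.shape:
            raise ValueError(f"shape mismatch {x.value.shape} vs {xh.value.shape}")
    return (x_sc - xhat_sc).square().mean() + (x_bulk - xhat_bulk).square().mean()


def _center_normalize(z: Tensor) -> Tensor:
    """Subtract per-dimension batch means, then scale each row to unit
    L2 norm.  Norms are treated as constants so the penalty cannot be
    gamed by shrinking embeddings."""
    n = z.value.shape[0]
    if n > 1:
        z = z - Tensor(np.full((n, n), 1.0 / n)) @ z
    norms = np.linalg.norm(z.value, axis=1, keepdims=True)
    return z * Tensor(1.0 / np.maximum(norms, 1e-12))


def loss_diff(z_sc: LatentEmbedding, z_bulk: LatentEmbedding) -> Tensor:
    """Orthogonality penalty between private and shared embeddings.

    Squared Frobenius norm of the cross-correlation of the batch-centered,
    row-L2-normalized embeddings, per domain, each scaled by its batch
    size.  Centering and normalization (standard in domain-separation
    encoders) make the penalty scale- and offset-free: driving embedding
    norms to zero or sharing a large mean component does not change it,
    only genuine correlation between private and shared coordinates does.
    """
    total = Tensor(0.0)
    for z in (z_sc, z_bulk):
        if z.z_private is None:
            continue
        n = z.z_private.value.shape[0]
        cross = _center_normalize(z.z_private).T @ _center_normalize(z.z_shared)
        total = total + cross.square().sum() * (1.0 / n)
    return total


def loss_sparse(x_sc, x_bulk, params: ModelParameters, z_sc, z_bulk) -> Tensor:
    """Masked-reconstruction loss, fitted on the offset-shifted matrix
    (see ``ArchitectureConfig.sparse_target_offset``)."""
    off = params.arch.sparse_target_offset
    x_sc = Tensor(np.asarray(x_sc if not isinstance(x_sc, Tensor) else x_sc.value) + off)
    x_bulk = Tensor(
        np.asarray(x_bulk if not isinstance(x_bulk, Tensor) else x_bulk.value) + off
    )
    return (x_sc - sparse_decode(z_sc, params)).square().mean() + (
        x_bulk - sparse_decode(z_bulk, params)
    ).square().mean()


def total_losses(
    x_bulk,
    x_sc,
    params: ModelParameters,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, Tensor]:
    """Full forward pass returning recon/diff/sparse/ae/train losses.

    L_AE = L_recon + r1 * L_diff;  L_train = L_AE + r2 * L_sparse.
    The diff term is skipped in base_ae mode, the sparse term in all
    modes without a pathway mask.
    """
    arch = params.arch
    zb = encode(x_bulk, params, "bulk", train=train, rng=rng)
    zs = encode(x_sc, params, "sc", train=train, rng=rng)
    recon = loss_recon(x_sc, x_bulk, decode(zs, params), decode(zb, params))
    out = {"recon": recon}
    if arch.mode == "base_ae":
        out["diff"] = Tensor(0.0)
        out["ae"] = recon
    else:
        out["diff"] = loss_diff(zs, zb)
        out["ae"] = recon + arch.r1 * out["diff"]
    if params.sparse_W is not None:
        out["sparse"] = loss_sparse(x_sc, x_bulk, params, zs.z_shared, zb.z_shared)
        out["train"] = out["ae"] + arch.r2 * out["sparse"]
    else:
        out["sparse"] = Tensor(0.0)
        out["train"] = out["ae"]
    return out


def bce_loss(y, p) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped to [1e-7, 1-1e-7]."""
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    pt = p if isinstance(p, Tensor) else Tensor(p)
    if pt.value.size != y.size:
        raise ValueError(f"length mismatch: {y.size} labels, {pt.value.size} probs")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    eps = 1e-7
    flat = pt if pt.value.ndim == 1 else pt @ Tensor(np.ones((pt.value.shape[1], 1)))
    pc = flat.clip(eps, 1.0 - eps)
    ymat = y.reshape(pc.value.shape)
    ll = Tensor(ymat) * pc.log() + Tensor(1.0 - ymat) * (Tensor(1.0) - pc).log()
    return -ll.mean()


# -- optimizer ---------------------------------------------------------------


class Adam:
    """Adam with the standard bias correction; state is per-parameter."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
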