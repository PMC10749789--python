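"""The full histology→expression network and its fitting interface.

The network maps each spot's H&E patch through an omni-dimensional dynamic
convolution stack and a capsule routing stage to a visual feature, fuses it
with learned array-coordinate embeddings, models cross-spot dependencies
with a transformer encoder over the whole section, refines features on the
4-nearest-neighbour spot graph with graph attention, and projects to the
gene panel.  Training minimises mean squared error against depth-normalised
log expression, one section per optimisation step, with Adam.

The public surface follows the statsmodels idiom:

    model = SpatialExpressionModel(sections, config)
    res = model.fit(seed=0)           # -> FitResults
    pred = res.predict(section)       # (N_spots, n_genes)
    report = loocv(sections, config)  # -> EvalReport with summary()

Any of the four modules can be replaced by an identity for ablation via
``ModelConfig.ablate``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Adam, Tensor
from .capsule import CapsuleStage
from .fusion_vit import (PositionEmbedding, ViTEncoder, embed_positions, fuse)
from .io import ExpressionMatrix, PatchStack, Section, extract_patches
from .metrics import pcc, pcc_pvalue, rank_genes
from .odconv import ODConv
from .preprocess import normalize
from .spatial_gat import GATStage, SpotGraph, build_knn_graph

__all__ = ["ModelConfig", "SpatialExpressionModel", "FitResults",
           "EvalReport", "loocv"]


@dataclass
class ModelConfig:
    """Every open architecture/optimisation hyperparameter.

    Defaults are desk-scale: small enough that a full leave-one-out run
    over a few 64-spot sections finishes in minutes on one CPU, while
    keeping every module of the architecture active.
    """

    # patch handling
    patch_size: int = 112
    patch_pool: int = 4             # average-pool factor before the conv stack
    # dynamic convolution stack
    odconv_widths: tuple = (8, 16)
    odconv_pools: tuple = (2, 7)    # avg-pool factor after each layer
    odconv_k: int = 3
    odconv_n: int = 4               # candidate kernels per layer
    kernel_attention: str = "sigmoid"
    # capsule stage
    caps_dim: int = 16
    caps_n_out: int = 8
    caps_d_out: int = 16
    # position embedding + transformer
    pos_dim: int = 16
    d_model: int = 64
    vit_depth: int = 2
    vit_heads: int = 4
    # graph attention
    gat_k: int = 4
    gat_leaky_slope: float = 0.2
    gat_coords: str = "pixel"
    # head / training
    n_genes: int = 20
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3      # decoupled L2 shrinkage
    epochs: int = 200
    augment: bool = True            # dihedral patch flips + coordinate jitter
    coord_jitter: int = 3           # max random array-coordinate translation
    seed: int = 0
    ablate: str | None = None       # one of odconv|capsule|vit|gat

    def __post_init__(self):
        if self.ablate not in (None, "odconv", "capsule", "vit", "gat"):
            raise ValueError(f"unknown ablation target {self.ablate!r}")
        if self.patch_size % self.patch_pool:
            raise ValueError("patch_pool must divide patch_size")
        if len(self.odconv_pools) != len(self.odconv_widths):
            raise ValueError("odconv_pools must pair with odconv_widths")
        size = self.patch_size // self.patch_pool
        for p in self.odconv_pools:
            if size % p:
                raise ValueError(
                    f"pool factor {p} does not divide feature size {size}")
            size //= p

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("odconv_widths", "odconv_pools"):
            d[key] = list(d[key])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in ("odconv_widths", "odconv_pools"):
            d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _divisor_at_most(n: int, target: int) -> int:
    for d in range(target, 0, -1):
        if n % d == 0:
            return d
    return 1


class _Network:
    """Parameter container + forward pass; built once per fit."""

    def __init__(self, cfg: ModelConfig, max_x: int, max_y: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        size = cfg.patch_size // cfg.patch_pool          # e.g. 112/4 = 28
        self.odconvs: list[ODConv] = []
        c = 3
        if cfg.ablate != "odconv":
            for width in cfg.odconv_widths:
                self.odconvs.append(ODConv(
                    c, width, k=cfg.odconv_k, n=cfg.odconv_n,
                    kernel_attention=cfg.kernel_attention, rng=rng))
                c = width
        for p in cfg.odconv_pools:
            size //= p                                   # pool after each layer
        self.feat_spatial = size
        flat = c * size * size
        if cfg.ablate != "capsule":
            caps_dim = _divisor_at_most(flat, cfg.caps_dim)
            self.capsule = CapsuleStage(
                c, size, size, caps_dim=caps_dim, n_out=cfg.caps_n_out,
                d_out=cfg.caps_d_out, k=cfg.odconv_k, rng=rng)
            d_f = self.capsule.out_features
        else:
            self.capsule = None
            d_f = flat                                   # identity: flatten map
        self.pos = PositionEmbedding(max_x, max_y, cfg.pos_dim, rng=rng)
        self.W_fuse = Tensor(
            rng.normal(0, np.sqrt(1.0 / (d_f + 2 * cfg.pos_dim)),
                       size=(d_f + 2 * cfg.pos_dim, cfg.d_model)),
            requires_grad=True)
        self.b_fuse = Tensor(np.zeros(cfg.d_model), requires_grad=True)
        self.vit = (ViTEncoder(cfg.d_model, depth=cfg.vit_depth,
                               heads=cfg.vit_heads, rng=rng)
                    if cfg.ablate != "vit" else None)
        if cfg.ablate != "gat":
            self.gat = GATStage(cfg.d_model, cfg.n_genes,
                                leaky_slope=cfg.gat_leaky_slope, rng=rng)
            self.W_out = self.b_out = None
        else:
            self.gat = None
            self.W_out = Tensor(rng.normal(0, np.sqrt(1.0 / cfg.d_model),
                                           size=(cfg.d_model, cfg.n_genes)),
                                requires_grad=True)
            self.b_out = Tensor(np.zeros(cfg.n_genes), requires_grad=True)

    def parameters(self) -> list:
        ps = []
        for layer in self.odconvs:
            ps += layer.parameters()
        if self.capsule is not None:
            ps += self.capsule.parameters()
        ps += self.pos.parameters() + [self.W_fuse, self.b_fuse]
        if self.vit is not None:
            ps += self.vit.parameters()
        if self.gat is not None:
            ps += self.gat.parameters()
        else:
            ps += [self.W_out, self.b_out]
        return ps

    def forward(self, patches: Tensor, spots, graph: SpotGraph) -> Tensor:
        cfg = self.cfg
        x = patches if isinstance(patches, Tensor) else Tensor(patches)
        if cfg.patch_pool > 1:
            x = x.avg_pool2d(cfg.patch_pool)
        if self.odconvs:
            for layer, pool in zip(self.odconvs, cfg.odconv_pools):
                x = layer(x).relu().avg_pool2d(pool)
        else:
            for pool in cfg.odconv_pools:
                x = x.avg_pool2d(pool)
        if self.capsule is not None:
            feats = self.capsule(x)                       # (N, d_f)
        else:
            N = x.shape[0]
            feats = x.reshape(N, int(np.prod(x.shape[1:])))
        pos = embed_positions(spots, self.pos)
        seq = fuse(feats, pos, self.W_fuse, self.b_fuse)  # (N, d_model)
        if self.vit is not None:
            seq = self.vit(seq)
        if self.gat is not None:
            return self.gat(seq, graph)
        return seq @ self.W_out + self.b_out


class _CoordView:
    """array_x/array_y view used to feed transformed coordinates."""

    __slots__ = ("array_x", "array_y")

    def __init__(self, array_x, array_y):
        self.array_x = array_x
        self.array_y = array_y


def _augment_coords(spots, rng: np.random.Generator, max_x: int, max_y: int,
                    jitter: int) -> _CoordView:
    """Random dihedral transform + translation of the array grid.

    Spot identity cannot be read off the augmented coordinates, which
    forces the position embeddings to carry geometry rather than memorised
    per-spot expression; relative structure survives the transform.
    """
    x, y = spots.array_x.copy(), spots.array_y.copy()
    if rng.integers(2):
        x = x.max() - x
    if rng.integers(2):
        y = y.max() - y
    if x.max() <= max_y and y.max() <= max_x and rng.integers(2):
        x, y = y, x
    x = x + rng.integers(0, jitter + 1)
    y = y + rng.integers(0, jitter + 1)
    return _CoordView(x, y)


def _dihedral(patches: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random per-patch flip/rotation; expression is orientation-invariant."""
    out = patches.copy()
    ops = rng.integers(0, 8, size=len(patches))
    for i, op in enumerate(ops):
        p = out[i]
        if op & 1:
            p = p[:, :, ::-1]
        if op & 2:
            p = p[:, ::-1, :]
        if op & 4:
            p = np.swapaxes(p, 1, 2)
        out[i] = p
    return out


def _prepare_section(section: Section, cfg: ModelConfig):
    """Patches, normalised targets and the spot graph for one section."""
    if section.patches is not None:
        patches = section.patches
    else:
        if section.image is None:
            raise ValueError(
                f"section {section.section_id} has neither image nor patches")
        patches = extract_patches(section.image, section.spots,
                                  patch_size=cfg.patch_size)
    expr = section.expr
    if expr.state.value == "raw_counts":
        expr = normalize(expr)
    graph = build_knn_graph(section.spots, k=cfg.gat_k, coords=cfg.gat_coords)
    return patches.patches, expr.values.astype(np.float64), graph


class FitResults:
    """Trained parameters plus training diagnostics.

    Attributes
    ----------
    loss_history : list of per-epoch mean training MSE.
    config : the ModelConfig used.
    """

    def __init__(self, network: _Network, cfg: ModelConfig,
                 loss_history: list, gene_names: list, seed: int,
                 target_mean=None, target_std=None):
        self._network = network
        self.config = cfg
        self.loss_history = loss_history
        self.gene_names = gene_names
        self.seed = seed
        self.target_mean = target_mean
        self.target_std = target_std

    def predict(self, section: Section) -> np.ndarray:
        """Predicted normalised expression for every spot, (N, n_genes)."""
        patches, _, graph = _prepare_section(section, self.config)
        out = self._network.forward(Tensor(patches), section.spots,
                                    graph).data
        if self.target_mean is not None:
            out = out * self.target_std + self.target_mean
        return out.copy()

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Spatial expression model — fit summary",
            "=" * 46,
            f"config hash       {cfg.config_hash}",
            f"seed              {self.seed}",
            f"genes             {cfg.n_genes}",
            f"parameters        {sum(p.size for p in self._network.parameters())}",
            f"epochs            {len(self.loss_history)}",
            f"final train MSE   {self.loss_history[-1]:.5f}"
            if self.loss_history else "final train MSE   n/a",
            f"ablated module    {cfg.ablate or 'none'}",
        ]
        return "\n".join(lines)


class SpatialExpressionModel:
    """Histology→expression model over a list of training sections.

    Parameters
    ----------
    sections : list of ``histoexpr.io.Section`` (image or patches +
        spot table + expression).  Raw counts are depth-normalised and
        log-transformed internally.
    config : ModelConfig; ``n_genes`` must match the sections' gene panel.
    """

    def __init__(self, sections: list, config: ModelConfig | None = None):
        if not sections:
            raise ValueError("need at least one training section")
        self.sections = list(sections)
        genes = sections[0].expr.gene_names
        for s in sections[1:]:
            if s.expr.gene_names != genes:
                raise ValueError("sections do not share a gene panel")
        cfg = config or ModelConfig(n_genes=len(genes))
        if cfg.n_genes != len(genes):
            raise ValueError(
                f"config.n_genes={cfg.n_genes} but sections carry "
                f"{len(genes)} genes")
        self.config = cfg
        self.gene_names = genes

    @classmethod
    def from_arrays(cls, images, spot_tables, expr_matrices,
                    config: ModelConfig | None = None):
        sections = [Section(spots=st, expr=em, image=im)
                    for im, st, em in zip(images, spot_tables, expr_matrices)]
        return cls(sections, config)

    def fit(self, epochs: int | None = None, seed: int | None = None,
            verbose: bool = False) -> FitResults:
        """Train with Adam, one section per step; deterministic given seed."""
        cfg = self.config
        epochs = epochs if epochs is not None else cfg.epochs
        seed = seed if seed is not None else cfg.seed
        rng = np.random.default_rng(seed)
        max_x = max(int(s.spots.array_x.max()) for s in self.sections)
        max_y = max(int(s.spots.array_y.max()) for s in self.sections)
        pad = cfg.coord_jitter if cfg.augment else 0
        # symmetric tables so the x/y-swap augmentation stays in bounds
        table_max = max(max_x, max_y) + pad
        net = _Network(cfg, table_max, table_max, rng)
        prepared = [_prepare_section(s, cfg) for s in self.sections]
        # per-gene standardisation of the regression target: every gene
        # contributes comparably to the MSE; predictions are mapped back
        all_t = np.vstack([t for _, t, _ in prepared])
        t_mean = all_t.mean(axis=0)
        t_std = all_t.std(axis=0)
        t_std[t_std == 0] = 1.0
        prepared = [(p, (t - t_mean) / t_std, g) for p, t, g in prepared]
        opt = Adam(net.parameters(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
        aug_rng = np.random.default_rng(
            np.random.SeedSequence((seed, 0xA06)))
        history = []
        for _ in range(epochs):
            losses = []
            for (patches, target, graph), section in zip(prepared,
                                                         self.sections):
                coords = section.spots
                if cfg.augment:
                    patches = _dihedral(patches, aug_rng)
                    coords = _augment_coords(section.spots, aug_rng,
                                             table_max, table_max,
                                             cfg.coord_jitter)
                opt.zero_grad()
                out = net.forward(Tensor(patches), coords, graph)
                diff = out - Tensor(target)
                loss = (diff * diff).mean()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {len(history):3d}  mse {history[-1]:.5f}")
        return FitResults(net, cfg, history, self.gene_names, seed,
                          target_mean=t_mean, target_std=t_std)


# ------------------------------------------------------------------- LOOCV

class EvalReport:
    """Cross-validated evaluation: per-gene PCC/p per held-out section."""

    def __init__(self, gene_names: list, config: ModelConfig, seed: int):
        self.gene_names = list(gene_names)
        self.config = config
        self.seed = seed
        self.section_ids: list = []
        self.pcc_per_gene: dict = {}        # section -> (G,) array
        self.pvalue_per_gene: dict = {}
        self.predictions: dict = {}         # section -> (N, G) array
        self.ari_per_section: dict = {}

    def add_section(self, section_id: str, pccs, pvals, pred):
        self.section_ids.append(section_id)
        self.pcc_per_gene[section_id] = np.asarray(pccs, dtype=float)
        self.pvalue_per_gene[section_id] = np.asarray(pvals, dtype=float)
        self.predictions[section_id] = np.asarray(pred, dtype=float)

    def mean_pcc_per_section(self) -> dict:
        """Mean over genes of per-gene PCC (NaN-flagged genes excluded)."""
        return {sid: float(np.nanmean(v))
                for sid, v in self.pcc_per_gene.items()}

    @property
    def mean_pcc(self) -> float:
        all_vals = np.concatenate(
            [self.pcc_per_gene[s] for s in self.section_ids])
        return float(np.nanmean(all_vals))

    def gene_ranking(self) -> list:
        p = np.vstack([self.pvalue_per_gene[s] for s in self.section_ids])
        return rank_genes(self.gene_names, p)

    def to_dict(self) -> dict:
        return {
            "provenance": {"config_hash": self.config.config_hash,
                           "seed": self.seed},
            "mean_pcc": self.mean_pcc,
            "mean_pcc_per_section": self.mean_pcc_per_section(),
            "pcc_per_gene": {s: v.tolist()
                             for s, v in self.pcc_per_gene.items()},
            "pvalue_per_gene": {s: v.tolist()
                                for s, v in self.pvalue_per_gene.items()},
            "gene_ranking": self.gene_ranking(),
            "ari_per_section": dict(self.ari_per_section),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        per_sec = self.mean_pcc_per_section()
        lines = ["Leave-one-out evaluation", "=" * 46,
                 f"config hash   {self.config.config_hash}",
                 f"seed          {self.seed}",
                 f"sections      {len(self.section_ids)}",
                 f"genes         {len(self.gene_names)}",
                 f"mean PCC      {self.mean_pcc:.4f}", "",
                 "per-section mean PCC:"]
        for sid in self.section_ids:
            extra = (f"   ARI {self.ari_per_section[sid]:.3f}"
                     if sid in self.ari_per_section else "")
            lines.append(f"  {sid:<16s} {per_sec[sid]:+.4f}{extra}")
        top = self.gene_ranking()[:5]
        lines += ["", "top genes by mean -log10 p: " + ", ".join(map(str, top))]
        return "\n".join(lines)


def loocv(sections: list, config: ModelConfig | None = None,
          epochs: int | None = None, seed: int | None = None,
          verbose: bool = False) -> EvalReport:
    """Leave-one-out cross-validation over sections.

    For every section, trains on the remaining sections and predicts the
    held-out spots; records per-gene PCC and p-values.  Deterministic
    given the seed.
    """
    if len(sections) < 2:
        raise ValueError("leave-one-out needs at least 2 sections")
    cfg = config or ModelConfig(n_genes=len(sections[0].expr.gene_names))
    seed = seed if seed is not None else cfg.seed
    report = EvalReport(sections[0].expr.gene_names, cfg, seed)
    for held in range(len(sections)):
        train = [s for i, s in enumerate(sections) if i != held]
        model = SpatialExpressionModel(train, cfg)
        res = model.fit(epochs=epochs, seed=seed, verbose=verbose)
        test = sections[held]
        pred = res.predict(test)
        expr = test.expr
        truth = (normalize(expr).values
                 if expr.state.value == "raw_counts" else expr.values)
        n = truth.shape[0]
        pccs = [pcc(truth[:, j], pred[:, j]) for j in range(truth.shape[1])]
        pvals = [pcc_pvalue(r, n) if not np.isnan(r) else float("nan")
                 for r in pccs]
        report.add_section(test.section_id, pccs, pvals, pred)
        if verbose:
            print(f"held out {test.section_id}: "
                  f"mean PCC {np.nanmean(pccs):+.4f}")
    return report
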