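"""Self-contained synthetic sections with a known image→expression link.

Each section is an H&E-like RGB image of Gaussian "nuclei" blobs, a grid of
spots with array and pixel coordinates, and an overdispersed spot×gene
count matrix.  The causal path is deterministic: a smooth density field
D(x, y) controls where nuclei are placed (inhomogeneous thinning) and, at
the spot locations, drives latent expression programs

    z1 = standardised D at the spot,
    z2 = smooth field modulating nucleus radius,
    z3 = smooth field modulating the eosin/hematoxylin tint,

all three of which leave a visible signature in the local patch texture.
Programs are smoothed over the spot grid with a Gaussian kernel of
correlation length ``rho`` (array units), giving spatially autocorrelated
expression.  Gene means are a low-rank log-linear map μ = exp(b + β·zLᵀ)
and counts are negative-binomial with dispersion ``nb_size`` (variance
μ + μ²/size), emulating the overdispersion of real ST counts.

``ground_truth`` carries the density at spots, the program matrix z and
the loading matrix L, so an oracle predictor (ridge on the true z) can
upper-bound what any image-based model could recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, ExpressionState, Section, SpotTable

__all__ = ["SynthConfig", "GroundTruth", "make_section", "make_annotation",
           "make_dataset", "oracle_pcc"]


@dataclass
class SynthConfig:
    """Desk-scale defaults: 4 sections of 8×8 spots on 448×448 images."""

    n_sections: int = 4
    grid_rows: int = 8
    grid_cols: int = 8
    spot_spacing: int = 56          # pixels between spot centres
    n_genes: int = 20
    n_programs: int = 3
    blob_density: float = 60.0      # expected nuclei per unit density
    blob_radius: float = 4.0        # base nucleus radius, pixels
    beta: float = 1.0               # image-feature → expression strength
    rho: float = 2.0                # program correlation length, array units
    nb_size: float = 20.0           # NB dispersion (variance = μ + μ²/size)
    base_count: float = 50.0        # mean counts per gene at z = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_sections", "grid_rows", "grid_cols", "spot_spacing",
                     "n_genes", "n_programs", "nb_size", "base_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def image_size(self) -> tuple:
        return (self.grid_rows * self.spot_spacing,
                self.grid_cols * self.spot_spacing)


@dataclass
class GroundTruth:
    density_at_spots: np.ndarray    # (N,)
    z: np.ndarray                   # (N, n_programs)
    loadings: np.ndarray            # (n_genes, n_programs)
    density_field: np.ndarray       # (H, W)


def _smooth_grid_field(rng: np.random.Generator, rows: int, cols: int,
                       rho: float) -> np.ndarray:
    """Standardised smooth random field on the spot grid (row-major)."""
    raw = rng.normal(size=(rows, cols))
    if rho > 0:
        yy, xx = np.mgrid[0:rows, 0:cols]
        pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        w = np.exp(-d2 / (2 * rho ** 2))
        sm = (w @ raw.ravel()) / w.sum(axis=1)
    else:
        sm = raw.ravel()
    sm = sm - sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _loadings(rng: np.random.Generator, n_genes: int, n_programs: int
              ) -> np.ndarray:
    """Low-rank loading matrix; every gene loads mainly on one program.

    The density program (index 0) is the dominant expression axis — half
    the genes track it at full magnitude — mirroring how the annotated
    domain structure (tumour vs stroma content) dominates expression
    variation in real sections; the remaining programs are secondary.
    """
    L = 0.15 * rng.normal(size=(n_genes, n_programs))
    probs = np.full(n_programs, 0.5 / max(n_programs - 1, 1))
    probs[0] = 0.5 if n_programs > 1 else 1.0
    main = rng.choice(n_programs, size=n_genes, p=probs)
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    mags = np.where(main == 0, 1.0, 0.8)
    L[np.arange(n_genes), main] += signs * mags
    return L


def make_section(cfg: SynthConfig, section_index: int
                 ) -> tuple[np.ndarray, SpotTable, ExpressionMatrix, GroundTruth]:
    """Render one synthetic section (image, spots, counts, ground truth).

    Deterministic given ``cfg.seed`` and ``section_index``; the gene
    loading matrix is shared across sections of the same config (seeded by
    ``cfg.seed`` alone) so that cross-section training is meaningful.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        (cfg.seed, section_index)))
    H, W = cfg.image_size
    rows, cols = cfg.grid_rows, cfg.grid_cols
    sp = cfg.spot_spacing

    # --- smooth density field over the image: gradient + random bumps
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    phase = rng.uniform(0, 2 * np.pi)
    D = 0.5 + 0.45 * np.sin(2 * np.pi * xx / W + phase)
    for _ in range(3):
        cy_, cx_ = rng.uniform(0, H), rng.uniform(0, W)
        s = rng.uniform(0.15, 0.3) * min(H, W)
        D += 0.25 * np.exp(-((yy - cy_) ** 2 + (xx - cx_) ** 2) / (2 * s ** 2))
    D = np.clip(D, 0.02, None)
    D /= D.max()

    # --- spot grid (array coords col-major x = col, y = row)
    ar_y, ar_x = np.mgrid[0:rows, 0:cols]
    ar_x, ar_y = ar_x.ravel(), ar_y.ravel()
    px = ar_x * sp + sp / 2.0
    py = ar_y * sp + sp / 2.0
    if (px >= W).any() or (py >= H).any():
        raise ValueError("spot grid exceeds image for the given spacing")
    n_spots = rows * cols
    spots = SpotTable(
        spot_id=np.array([f"s{section_index}_{i}" for i in range(n_spots)]),
        array_x=ar_x, array_y=ar_y, pixel_x=px, pixel_y=py,
        section_id=f"synth{section_index}")

    # --- latent programs at spots
    d_spot = D[py.astype(int), px.astype(int)]
    z1 = (d_spot - d_spot.mean()) / (d_spot.std() + 1e-12)
    z2 = _smooth_grid_field(rng, rows, cols, cfg.rho)
    z3 = _smooth_grid_field(rng, rows, cols, cfg.rho)
    z = np.column_stack([z1, z2, z3])[:, :cfg.n_programs]

    # --- render nuclei; radius/tint fields echo z2/z3 in the texture
    radius_spot = cfg.blob_radius * (1.0 + 0.35 * np.tanh(z2))
    tint_spot = 0.5 * np.tanh(z3)
    img = np.empty((H, W, 3))
    img[..., 0] = 0.92  # eosin-pink background
    img[..., 1] = 0.80
    img[..., 2] = 0.88
    dens = np.zeros((H, W))
    spot_of_pixel_r = np.clip(yy.astype(int) // sp, 0, rows - 1)
    spot_of_pixel_c = np.clip(xx.astype(int) // sp, 0, cols - 1)
    n_blob = rng.poisson(cfg.blob_density * D.mean() * rows * cols)
    # thinning: accept candidate centres with probability D
    cand_y = rng.uniform(0, H, size=3 * n_blob + 30)
    cand_x = rng.uniform(0, W, size=3 * n_blob + 30)
    accept = rng.uniform(size=cand_y.size) < D[cand_y.astype(int),
                                               cand_x.astype(int)]
    by, bx = cand_y[accept][:n_blob], cand_x[accept][:n_blob]
    for cy_, cx_ in zip(by, bx):
        si = spot_of_pixel_r[int(cy_), 0] * cols + spot_of_pixel_c[0, int(cx_)]
        r = radius_spot[si]
        t = tint_spot[si]
        w = int(np.ceil(3 * r))
        y0, y1 = max(int(cy_) - w, 0), min(int(cy_) + w + 1, H)
        x0, x1 = max(int(cx_) - w, 0), min(int(cx_) + w + 1, W)
        gy, gx = np.mgrid[y0:y1, x0:x1].astype(float)
        g = np.exp(-((gy - cy_) ** 2 + (gx - cx_) ** 2) / (2 * (r / 1.5) ** 2))
        dens[y0:y1, x0:x1] += g
        # hematoxylin-purple nucleus, tint shifting blue<->red with z3
        img[y0:y1, x0:x1, 0] -= g * (0.55 - 0.15 * t)
        img[y0:y1, x0:x1, 1] -= g * 0.55
        img[y0:y1, x0:x1, 2] -= g * (0.25 + 0.15 * t)
    img = np.clip(img, 0.0, 1.0)
    image = (img * 255).round().astype(np.uint8)

    # --- expression: low-rank log-linear in z, NB noise
    L = _loadings(np.random.default_rng(cfg.seed), cfg.n_genes, cfg.n_programs)
    eta = cfg.beta * (z @ L.T)
    mu = cfg.base_count * np.exp(eta - eta.mean(axis=0, keepdims=True))
    p = cfg.nb_size / (cfg.nb_size + mu)
    counts = rng.negative_binomial(cfg.nb_size, p)
    expr = ExpressionMatrix(
        counts, [f"g{j}" for j in range(cfg.n_genes)],
        state=ExpressionState.RAW_COUNTS, spot_ids=spots.spot_id.copy())
    gt = GroundTruth(density_at_spots=d_spot, z=z, loadings=L,
                     density_field=D)
    return image, spots, expr, gt


def make_annotation(ground_truth: GroundTruth, k: int) -> np.ndarray:
    """Quantile-bin the latent density at spots into ``k`` spatial domains."""
    if k < 2:
        raise ValueError("need at least 2 annotation domains")
    d = ground_truth.density_at_spots
    qs = np.quantile(d, np.linspace(0, 1, k + 1)[1:-1])
    return np.digitize(d, qs)


def make_dataset(cfg: SynthConfig | None = None
                 ) -> tuple[list[Section], list[GroundTruth]]:
    """All sections of a config as ``histoexpr.io.Section`` objects."""
    cfg = cfg or SynthConfig()
    sections, truths = [], []
    for idx in range(cfg.n_sections):
        image, spots, expr, gt = make_section(cfg, idx)
        sections.append(Section(spots=spots, expr=expr, image=image))
        truths.append(gt)
    return sections, truths


def oracle_pcc(cfg: SynthConfig | None = None, ridge: float = 1e-6) -> float:
    """Mean per-gene PCC of a linear predictor given the *true* programs.

    Fits normalised expression on z pooled over all sections and scores
    in-sample; this upper-bounds the image-based model and validates that
    the generator's signal path carries recoverable structure.
    """
    from .preprocess import normalize
    from .metrics import pcc
    cfg = cfg or SynthConfig()
    sections, truths = make_dataset(cfg)
    Z = np.vstack([t.z for t in truths])
    Y = np.vstack([normalize(s.expr).values for s in sections])
    X = np.column_stack([np.ones(len(Z)), Z])
    coef = np.linalg.solve(X.T @ X + ridge * np.eye(X.shape[1]), X.T @ Y)
    pred = X @ coef
    vals = [pcc(Y[:, j], pred[:, j]) for j in range(Y.shape[1])]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals))
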