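"""Section, gene and normalisation filters for raw ST count data.

Pipeline order: drop small sections (spot count must be strictly greater
than ``min_spots_per_section``); drop genes expressed (count > 0) in fewer
than ``min_spots_per_gene`` spots pooled across sections; per-spot
depth-normalise counts to ``scale_factor`` and natural-log transform with a
pseudocount of 1; keep the top ``n_hvg`` genes by pooled variance of the
normalised values.  The retained panel is the intersection of the presence
filter and the HVG ranking, which is why the final gene count can fall
below ``n_hvg``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .io import ExpressionMatrix, ExpressionState, Section

__all__ = ["PreprocessConfig", "filter_sections", "filter_genes",
           "select_hvg", "normalize", "run_preprocess"]


@dataclass
class PreprocessConfig:
    min_spots_per_section: int = 180
    min_spots_per_gene: int = 1000
    n_hvg: int = 1000
    scale_factor: float = 1e6

    def __post_init__(self):
        for name in ("min_spots_per_section", "min_spots_per_gene",
                     "n_hvg", "scale_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def filter_sections(sections: list, min_spots: int) -> list:
    """Keep sections whose spot count is strictly greater than ``min_spots``."""
    kept = [s for s in sections if _n_spots(s) > min_spots]
    if not kept:
        warnings.warn("no section passed the spot-count filter", stacklevel=2)
    return kept


def _n_spots(section) -> int:
    if isinstance(section, Section):
        return section.expr.n_spots
    if isinstance(section, tuple):          # (SpotTable, ExpressionMatrix)
        return section[1].n_spots
    return section.n_spots                  # bare ExpressionMatrix


def _expr_of(section) -> ExpressionMatrix:
    if isinstance(section, Section):
        return section.expr
    if isinstance(section, tuple):
        return section[1]
    return section


def filter_genes(sections: list, min_spots: int) -> np.ndarray:
    """Indices of genes expressed (count > 0) in ≥ ``min_spots`` spots pooled
    across all sections; all sections must share one gene namespace."""
    exprs = [_expr_of(s) for s in sections]
    names = exprs[0].gene_names
    for e in exprs[1:]:
        if e.gene_names != names:
            raise ValueError("sections do not share a gene namespace")
    pooled = sum((e.values > 0).sum(axis=0) for e in exprs)
    return np.flatnonzero(pooled >= min_spots)


def normalize(expr: ExpressionMatrix, scale: float = 1e6) -> ExpressionMatrix:
    """Depth-normalise each spot then log-transform.

    v_ij = ln(1 + scale * c_ij / sum_j c_ij); an all-zero spot maps to an
    all-zero row.
    """
    if expr.state != ExpressionState.RAW_COUNTS:
        raise ValueError("normalize expects raw counts")
    counts = expr.values.astype(np.float64)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cpm = np.where(totals > 0, counts / totals * scale, 0.0)
    return ExpressionMatrix(np.log1p(cpm), expr.gene_names,
                            state=ExpressionState.NORMALIZED,
                            spot_ids=expr.spot_ids)


def select_hvg(sections: list, n: int, per_section: bool = False
               ) -> np.ndarray:
    """Indices of the ``n`` most variable genes of the normalised values.

    By default variance is computed over the sections pooled into one
    matrix; with ``per_section=True`` the result is the union of each
    section's own top-``n`` (useful when strong section effects would
    otherwise dominate the pooled ranking).  Ties at the cutoff break by
    gene-name lexicographic order.
    """
    exprs = [_expr_of(s) for s in sections]
    for e in exprs:
        if e.state != ExpressionState.NORMALIZED:
            raise ValueError("select_hvg expects normalised sections")
    names = exprs[0].gene_names
    if n >= len(names):
        if n > len(names):
            warnings.warn(f"n_hvg={n} exceeds gene count {len(names)}; "
                          "keeping all genes", stacklevel=2)
        return np.arange(len(names))

    def top_n(values):
        var = values.var(axis=0)
        order = sorted(range(len(names)), key=lambda i: (-var[i], names[i]))
        return order[:n]

    if per_section:
        keep = set()
        for e in exprs:
            keep.update(top_n(e.values))
        return np.array(sorted(keep))
    pooled = np.vstack([e.values for e in exprs])
    return np.array(sorted(top_n(pooled)))


def run_preprocess(sections: list, cfg: PreprocessConfig | None = None):
    """Run the full filter/normalise pipeline over a list of sections.

    Returns ``(processed_sections, gene_names, provenance)`` where
    provenance records spot/gene counts after every stage.
    """
    cfg = cfg or PreprocessConfig()
    exprs = [_expr_of(s) for s in sections]
    log = {"config": asdict(cfg),
           "input": {"sections": len(sections),
                     "spots": int(sum(e.n_spots for e in exprs)),
                     "genes": len(exprs[0].gene_names) if exprs else 0}}

    kept = filter_sections(sections, cfg.min_spots_per_section)
    log["after_section_filter"] = {
        "sections": len(kept),
        "spots": int(sum(_n_spots(s) for s in kept))}
    if not kept:
        return [], [], log

    presence_idx = filter_genes(kept, cfg.min_spots_per_gene)
    log["after_gene_filter"] = {"genes": int(len(presence_idx))}

    normed = []
    for s in kept:
        e = normalize(_expr_of(s), cfg.scale_factor)
        normed.append((s, e))
    hvg_idx = select_hvg([e for _, e in normed], cfg.n_hvg)
    log["after_hvg"] = {"genes": int(len(hvg_idx))}

    final_idx = np.intersect1d(presence_idx, hvg_idx)
    names = _expr_of(kept[0]).gene_names
    final_names = [names[i] for i in final_idx]
    log["final"] = {"genes": int(len(final_idx)),
                    "spots": log["after_section_filter"]["spots"]}

    out = []
    for s, e in normed:
        sub = ExpressionMatrix(e.values[:, final_idx], final_names,
                               state=ExpressionState.NORMALIZED,
                               spot_ids=e.spot_ids)
        if isinstance(s, Section):
            out.append(Section(spots=s.spots, expr=sub, image=s.image,
                               patches=s.patches))
        elif isinstance(s, tuple):
            out.append((s[0], sub))
        else:
            out.append(sub)
    return out, final_names, log
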