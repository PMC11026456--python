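"""Synthetic genes x cells count matrix with a planted LGR5-high
subpopulation and anticorrelated EZR expression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..expression_scoring import ERM_GENES, SIGNATURE_GENES, ExpressionMatrix

__all__ = ["ExpressionTruth", "gen_expression", "REQUIRED_GENES"]

REQUIRED_GENES = tuple(SIGNATURE_GENES) + tuple(ERM_GENES)


@dataclass
class ExpressionTruth:
    labels_high: np.ndarray  # bool per cell, planted LGR5-high
    mean_matrix: np.ndarray  # (n_genes, n_cells) expected counts
    params: dict


def gen_expression(
    n_cells: int = 1000,
    n_genes: int = 100,
    lgr5_high_fraction: float = 0.25,
    erm_anticorrelation: float = 1.0,
    noise: float = 0.3,
    seed: int = 0,
    *,
    signature_fold: float = 4.0,
    base_mean: float = 5.0,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Draw a count matrix with known group structure.

    A fraction ``lgr5_high_fraction`` of cells is planted LGR5-high:
    their five signature genes have ``signature_fold`` times the base
    mean.  EZR is reduced in the planted-high cells by a factor
    ``1 + erm_anticorrelation`` (0 = no effect, 1 = 2-fold lower).
    ``noise`` is the negative-binomial dispersion; ``noise = 0`` returns
    the expected means themselves (deterministic, perfectly separable),
    and also disables the log-normal per-cell size factors that
    otherwise scale each cell's library.
    """
    if not 0 < lgr5_high_fraction < 1:
        raise ValueError("lgr5_high_fraction must lie in (0, 1)")
    if erm_anticorrelation < 0:
        raise ValueError("erm_anticorrelation must be non-negative")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if n_genes < len(REQUIRED_GENES):
        raise ValueError(
            f"n_genes must be at least {len(REQUIRED_GENES)} to hold {REQUIRED_GENES}"
        )
    rng = np.random.default_rng(seed)

    gene_ids = list(REQUIRED_GENES) + [
        f"GENE{i:04d}" for i in range(n_genes - len(REQUIRED_GENES))
    ]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    n_high = max(1, int(round(lgr5_high_fraction * n_cells)))
    labels = np.zeros(n_cells, dtype=bool)
    labels[rng.choice(n_cells, size=n_high, replace=False)] = True

    # per-gene baseline means (filler genes vary log-normally)
    base = np.full(n_genes, base_mean)
    base[len(REQUIRED_GENES):] = base_mean * rng.lognormal(0.0, 0.5, n_genes - len(REQUIRED_GENES))

    mean = np.tile(base[:, None], (1, n_cells))
    sig_idx = [gene_ids.index(g) for g in SIGNATURE_GENES]
    ezr_idx = gene_ids.index("EZR")
    mean[np.ix_(sig_idx, np.where(labels)[0])] *= signature_fold
    mean[ezr_idx, labels] /= 1.0 + erm_anticorrelation

    if noise == 0:
        counts = mean.copy()
    else:
        size_factors = rng.lognormal(0.0, 0.3, n_cells)
        m = mean * size_factors[None, :]
        r = 1.0 / noise  # NB size parameter; variance = m + noise * m^2
        p = r / (r + m)
        counts = rng.negative_binomial(r, p).astype(float)

    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, state="raw")
    truth = ExpressionTruth(
        labels_high=labels,
        mean_matrix=mean,
        params={
            "lgr5_high_fraction": lgr5_high_fraction,
            "erm_anticorrelation": erm_anticorrelation,
            "noise": noise,
            "signature_fold": signature_fold,
            "seed": seed,
        },
    )
    return matrix, truth
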