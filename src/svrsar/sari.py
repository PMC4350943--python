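"""SAR continuity and discontinuity scoring (the SARI score components).

A compound data set's structure–activity relationship (SAR) information is
summarized by two scores over all compound pairs (i > j), built from the
Tanimoto similarity Tc(i, j) and the pKi potencies pot(i):

raw continuity
    ``cont_raw = 1 − Σ w_ij · Tc(i,j) / Σ w_ij`` with the potency weight
    ``w_ij = pot(i)·pot(j) / (1 + |pot(i) − pot(j)|)``. High continuity means
    structurally similar or dissimilar compounds with small-to-moderate
    potency variation dominate; since Tc ∈ [0, 1] the score lies in [0, 1].

raw discontinuity
    The mean of ``|pot(i) − pot(j)| · Tc(i,j)`` over qualifying pairs with
    ``Tc(i,j) ≥ t`` (the scheme's similarity threshold: 0.85 for MACCS-like,
    0.56 for ECFP4-like fingerprints). High discontinuity means many
    structural analogs with large potency gaps — activity cliffs are the
    extreme case. With zero qualifying pairs the score is *undefined* and an
    :class:`~svrsar.errors.UndefinedScoreError` is raised rather than
    silently reporting 0, which would mimic the very artifact this package
    is designed to expose.

Raw scores are normalized against an external reference panel of data sets:
each raw score is converted to a Z-score with the panel mean and sample
standard deviation and mapped to [0, 1] through the standard normal CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .data_io import DataSet
from .errors import DegeneratePanelError, UndefinedScoreError, ValidationError
from .similarity import pairwise_matrix


@dataclass(frozen=True)
class PairContribution:
    """Bookkeeping for one compound pair's score contribution (i > j)."""

    i: int
    j: int
    tc: float
    weight: float
    potency_gap: float
    qualifies: bool


@dataclass(frozen=True)
class PanelStats:
    """Reference-panel mean/sd (sample sd, ddof=1) of both raw scores."""

    cont_mean: float
    cont_sd: float
    disc_mean: float
    disc_sd: float
    n_sets: int

    def __post_init__(self):
        if self.n_sets < 2:
            raise DegeneratePanelError("panel stats need >= 2 panel sets")
        if not (self.cont_sd > 0 and self.disc_sd > 0):
            raise DegeneratePanelError("panel raw-score sd must be > 0")


@dataclass(frozen=True)
class SariScores:
    """Raw and panel-normalized continuity/discontinuity of one data set."""

    cont_raw: float
    disc_raw: float
    cont_norm: float | None
    disc_norm: float | None
    threshold_t: float
    n_qualifying_pairs: int


def pair_weight(pot_i: float, pot_j: float) -> float:
    """Potency weight w_ij = pot_i·pot_j / (1 + |pot_i − pot_j|); symmetric."""
    if not (math.isfinite(pot_i) and math.isfinite(pot_j)):
        raise ValidationError("pair_weight requires finite potencies")
    return pot_i * pot_j / (1.0 + abs(pot_i - pot_j))


def _upper(n: int):
    return np.triu_indices(n, k=1)


def raw_continuity(potencies: np.ndarray, sim_matrix: np.ndarray) -> float:
    """Weighted-mean-similarity complement over all pairs i > j."""
    p = np.asarray(potencies, dtype=float)
    n = p.size
    if n < 2:
        raise ValidationError("raw_continuity needs >= 2 compounds")
    iu, ju = _upper(n)
    gaps = np.abs(p[iu] - p[ju])
    w = p[iu] * p[ju] / (1.0 + gaps)
    tc = sim_matrix[iu, ju]
    return float(1.0 - np.sum(w * tc) / np.sum(w))


def raw_discontinuity(
    potencies: np.ndarray, sim_matrix: np.ndarray, t: float
) -> float:
    """Mean potency-gap-times-similarity over qualifying pairs (Tc >= t)."""
    p = np.asarray(potencies, dtype=float)
    n = p.size
    if n < 2:
        raise ValidationError("raw_discontinuity needs >= 2 compounds")
    if not (0.0 < t <= 1.0):
        raise ValidationError(f"threshold t must be in (0, 1], got {t}")
    iu, ju = _upper(n)
    tc = sim_matrix[iu, ju]
    mask = tc >= t
    if not mask.any():
        raise UndefinedScoreError(
            f"no compound pair with Tc >= {t}; discontinuity undefined"
        )
    gaps = np.abs(p[iu] - p[ju])[mask]
    return float(np.mean(gaps * tc[mask]))


def pair_contributions(
    potencies: np.ndarray, sim_matrix: np.ndarray, t: float
) -> list[PairContribution]:
    """Per-pair attribution (i > j) of both scores' ingredients."""
    p = np.asarray(potencies, dtype=float)
    iu, ju = _upper(p.size)
    out = []
    for i, j in zip(iu, ju):
        tc = float(sim_matrix[i, j])
        gap = float(abs(p[i] - p[j]))
        out.append(
            PairContribution(
                i=int(i), j=int(j), tc=tc,
                weight=pair_weight(p[i], p[j]),
                potency_gap=gap, qualifies=tc >= t,
            )
        )
    return out


def panel_stats(cont_raws, disc_raws) -> PanelStats:
    """Sample mean/sd of raw scores over a reference panel (>= 2 sets)."""
    c = np.asarray(cont_raws, dtype=float)
    d = np.asarray(disc_raws, dtype=float)
    if c.size < 2 or d.size < 2:
        raise DegeneratePanelError("panel_stats needs >= 2 panel sets")
    return PanelStats(
        cont_mean=float(c.mean()),
        cont_sd=float(c.std(ddof=1)),
        disc_mean=float(d.mean()),
        disc_sd=float(d.std(ddof=1)),
        n_sets=int(c.size),
    )


def normalize_score(raw: float, mean: float, sd: float) -> float:
    """Φ((raw − mean)/sd): Z-score mapped to [0, 1] via the normal CDF."""
    if not (sd > 0):
        raise DegeneratePanelError("normalize_score requires sd > 0")
    return float(ndtr((raw - mean) / sd))


def score_dataset(
    dataset: DataSet,
    stats: PanelStats | None = None,
    t: float | None = None,
    sim_matrix: np.ndarray | None = None,
    potencies: np.ndarray | None = None,
) -> SariScores:
    """Compute raw (and, given panel stats, normalized) SAR scores.

    ``t`` defaults to the dataset scheme's threshold; ``sim_matrix`` and
    ``potencies`` allow reusing a precomputed similarity matrix and scoring
    predicted rather than observed potencies over the *same* structures.
    """
    if t is None:
        t = dataset.scheme.tc_threshold
    if sim_matrix is None:
        sim_matrix = pairwise_matrix(dataset)
    if potencies is None:
        potencies = dataset.potencies()
    cont = raw_continuity(potencies, sim_matrix)
    disc = raw_discontinuity(potencies, sim_matrix, t)
    iu, ju = _upper(len(potencies))
    n_qual = int(np.count_nonzero(sim_matrix[iu, ju] >= t))
    if stats is None:
        cont_n = disc_n = None
    else:
        cont_n = normalize_score(cont, stats.cont_mean, stats.cont_sd)
        disc_n = normalize_score(disc, stats.disc_mean, stats.disc_sd)
    return SariScores(
        cont_raw=cont, disc_raw=disc, cont_norm=cont_n, disc_norm=disc_n,
        threshold_t=float(t), n_qualifying_pairs=n_qual,
    )
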