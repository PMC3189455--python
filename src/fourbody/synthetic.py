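"""Seeded synthetic structures, corpora and labeled mutant datasets.

Real inputs to this pipeline — crystallographic C-alpha traces, a large
structure corpus for potential training, and wet-lab activity labels — are
external data.  This module generates stand-ins with the statistical
structure the pipeline assumes, so every stage is testable offline:

* **Traces** are self-avoiding random walks with the ~3.8 Angstrom CA-CA
  virtual bond of real backbones, mild directional persistence, and a
  self-avoidance radius; they are gap-free in general position by
  construction.
* **Corpora** are collections of independent traces (per-structure
  subseeds), optionally with biased amino-acid composition.
* **Mutant datasets** sample single-site substitutions and assign binary
  activity by rule: ``"ec-sum"`` thresholds the summed EC scores of the
  residual profile (so the signal lives in the features by construction,
  with controllable class skew, separation margin and label noise);
  ``"position-cluster"`` makes a designated fraction of positions
  inactive-prone, mimicking positional clustering of deleterious sites.

Every output is a pure function of its parameters including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import AA_ALPHABET, CAlphaTrace, ResiduePoint
from .tessellation import Tessellation, tessellate
from .potential import PotentialTable
from .mutagenesis import (
    ACTIVE,
    INACTIVE,
    MutantRecord,
    all_single_site_mutations,
    feature_matrix,
)

__all__ = [
    "SyntheticSpec",
    "GenerationError",
    "generate_trace",
    "generate_corpus",
    "generate_mutant_dataset",
]


class GenerationError(RuntimeError):
    """The rejection budget for the self-avoiding walk was exhausted."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults emulate the shape of the real inputs: chains comparable to a
    small enzyme domain, a CA-CA step of 3.8 Angstrom, uniform composition,
    and an even active/inactive split unless a skew is requested (the real
    datasets range from near-balance to an ~0.86 active fraction).
    """

    n_residues: int = 80
    n_structures: int = 25
    step: float = 3.8
    min_separation: float = 4.0
    composition_bias: dict[str, float] | None = None
    skew: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.min_separation >= 2 * self.step:
            raise ValueError("min_separation must be below twice the step")
        if not 0.0 < self.skew < 1.0:
            raise ValueError("skew must be in (0, 1)")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _composition(spec: SyntheticSpec) -> np.ndarray:
    if spec.composition_bias is None:
        return np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET))
    w = np.array([spec.composition_bias.get(aa, 1.0) for aa in AA_ALPHABET])
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("composition_bias weights must be nonnegative, not all 0")
    return w / w.sum()


def generate_trace(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    source_id: str = "synthetic",
) -> CAlphaTrace:
    """One self-avoiding walk trace, deterministic per seed.

    Consecutive points are exactly ``spec.step`` apart; every non-adjacent
    pair is at least ``spec.min_separation`` apart (rejection sampling with
    directional persistence, restarting the walk when stuck).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if n < 4:
        raise ValueError("need at least 4 residues")
    probs = _composition(spec)
    for _attempt in range(50):
        pts = np.zeros((n, 3))
        direction = _unit(rng.standard_normal(3))
        ok = True
        for i in range(1, n):
            placed = False
            for _try in range(200):
                cand_dir = _unit(direction + 0.9 * rng.standard_normal(3))
                cand = pts[i - 1] + spec.step * cand_dir
                if i >= 2:
                    d = np.linalg.norm(pts[: i - 1] - cand, axis=1)
                    if d.min() < spec.min_separation:
                        continue
                pts[i] = cand
                direction = cand_dir
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            aas = rng.choice(list(AA_ALPHABET), size=n, p=probs)
            residues = [
                ResiduePoint(i + 1, str(i + 1), aas[i], pts[i]) for i in range(n)
            ]
            return CAlphaTrace(chain_id="A", residues=residues, source_id=source_id)
    raise GenerationError(
        "self-avoiding walk rejection budget exhausted; relax min_separation"
    )


def generate_corpus(spec: SyntheticSpec) -> list[CAlphaTrace]:
    """Independent traces from per-structure subseeds."""
    if spec.n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_structures)
    return [
        generate_trace(spec, rng=np.random.default_rng(ss), source_id=f"synth{i:03d}")
        for i, ss in enumerate(children)
    ]


def _dense_positions(
    candidates: list[MutantRecord],
    s: np.ndarray,
    tau: float,
    eligible: np.ndarray,
    n_mutants: int,
    skew: float,
    min_per_position: int,
    rng: np.random.Generator,
) -> list[int]:
    """Greedy position selection for the "per-position" coverage scheme.

    Positions offering >= min_per_position eligible candidates are added
    one at a time, always picking (with seeded tie-breaking) the position
    whose full eligible set moves the running active fraction closest to
    the target skew; all its eligible candidates are taken.
    """
    pools: dict[int, list[int]] = {}
    for i, m in enumerate(candidates):
        if eligible[i]:
            pools.setdefault(m.position, []).append(i)
    pools = {p: v for p, v in pools.items() if len(v) >= min_per_position}
    if sum(len(v) for v in pools.values()) < n_mutants:
        raise ValueError(
            "not enough eligible candidates in well-covered positions; lower "
            "margin_sd, min_per_position or n_mutants"
        )
    chosen: list[int] = []
    n_active = 0
    remaining = set(pools)
    while len(chosen) < n_mutants and remaining:
        best_score = None
        ties: list[int] = []
        for p in sorted(remaining):
            idx = pools[p]
            a = sum(1 for i in idx if s[i] > tau)
            score = abs((n_active + a) / (len(chosen) + len(idx)) - skew)
            if best_score is None or score < best_score - 1e-12:
                best_score = score
                ties = [p]
            elif abs(score - best_score) <= 1e-12:
                ties.append(p)
        pick = int(ties[rng.integers(len(ties))])
        remaining.discard(pick)
        idx = pools[pick]
        if len(chosen) + len(idx) > n_mutants:
            idx = list(rng.choice(idx, size=n_mutants - len(chosen), replace=False))
        chosen.extend(idx)
        n_active += sum(1 for i in idx if s[i] > tau)
    return chosen


def generate_mutant_dataset(
    trace: CAlphaTrace,
    table: PotentialTable | None,
    n_mutants: int,
    rule: str = "ec-sum",
    skew: float = 0.5,
    noise: float = 0.0,
    margin_sd: float = 0.0,
    seed: int = 0,
    tess: Tessellation | None = None,
    inactive_position_fraction: float | None = None,
    coverage: str = "uniform",
    min_per_position: int = 4,
) -> list[MutantRecord]:
    """Sample labeled single-site mutants of one structure.

    Parameters
    ----------
    trace, table, tess
        The wild-type structure, a trained potential (required for
        ``"ec-sum"``), and optionally its precomputed tessellation.
    n_mutants
        How many of the 19N possible substitutions to return (sampled
        without replacement).
    rule
        ``"ec-sum"``: activity = sign of the residual-profile component sum
        relative to a threshold placed at the (1 - skew) quantile over all
        19N candidates, so the active fraction matches ``skew``.
        ``"position-cluster"``: a seeded set of positions (a
        ``1 - skew`` fraction by default) is inactive, the rest active.
    noise
        Bernoulli label-flip probability applied after rule labeling.
    margin_sd
        For ``"ec-sum"``: exclude candidates whose component sum lies
        within ``margin_sd`` standard deviations of the threshold, leaving
        a separation margin between the classes.
    seed
        Drives candidate sampling, thresholding ties and noise.
    coverage
        Candidate sampling scheme for ``"ec-sum"``.  ``"uniform"``: draw
        individual candidates, stratified to hit ``skew`` exactly — some
        positions then contribute a single mutant.  ``"per-position"``:
        take *all* eligible candidates of greedily chosen positions that
        offer at least ``min_per_position`` of them, approximating ``skew``
        while guaranteeing dense position coverage — the structure of real
        mutagenesis panels, which carry many mutants at every scanned
        position.
    min_per_position
        Minimum eligible candidates a position must offer to be used by
        the ``"per-position"`` scheme.

    Raises
    ------
    ValueError
        If more mutants are requested than exist (or than remain eligible
        after the margin exclusion).
    """
    if not 0.0 < skew < 1.0:
        raise ValueError("skew must be in (0, 1)")
    rng = np.random.default_rng(seed)
    candidates = all_single_site_mutations(trace)
    if n_mutants > len(candidates):
        raise ValueError(
            f"requested {n_mutants} mutants but only {len(candidates)} single-site "
            "substitutions exist"
        )

    if rule == "ec-sum":
        if table is None:
            raise ValueError("rule 'ec-sum' needs a trained potential table")
        if tess is None:
            tess = tessellate(trace)
        X, _ = feature_matrix(trace, tess, table, candidates)
        s = X.sum(axis=1)
        tau = float(np.quantile(s, 1.0 - skew))
        margin = margin_sd * float(np.std(s))
        eligible = np.abs(s - tau) > margin
        if coverage == "uniform":
            pos_idx = np.flatnonzero((s > tau) & eligible)
            neg_idx = np.flatnonzero((s <= tau) & eligible)
            n_active = int(round(n_mutants * skew))
            n_inactive = n_mutants - n_active
            if n_active > len(pos_idx) or n_inactive > len(neg_idx):
                raise ValueError(
                    "not enough eligible candidates at this skew/margin; lower "
                    "margin_sd or n_mutants"
                )
            chosen = np.concatenate([
                rng.choice(pos_idx, size=n_active, replace=False),
                rng.choice(neg_idx, size=n_inactive, replace=False),
            ])
        elif coverage == "per-position":
            chosen = _dense_positions(
                candidates, s, tau, eligible, n_mutants, skew,
                min_per_position, rng,
            )
        else:
            raise ValueError(f"unknown coverage scheme {coverage!r}")
        labels = np.where(s[np.asarray(chosen)] > tau, ACTIVE, INACTIVE)
    elif rule == "position-cluster":
        frac = (
            inactive_position_fraction
            if inactive_position_fraction is not None
            else 1.0 - skew
        )
        positions = np.arange(1, len(trace) + 1)
        n_inact_pos = int(round(frac * len(positions)))
        inactive_pos = set(
            rng.choice(positions, size=n_inact_pos, replace=False).tolist()
        )
        chosen = rng.choice(len(candidates), size=n_mutants, replace=False)
        labels = np.array([
            INACTIVE if candidates[i].position in inactive_pos else ACTIVE
            for i in chosen
        ])
    else:
        raise ValueError(f"unknown activity rule {rule!r}")

    order = rng.permutation(len(chosen))
    records = []
    for j in order:
        c = candidates[int(chosen[j])]
        label = int(labels[j])
        if noise > 0 and rng.random() < noise:
            label = -label
        records.append(MutantRecord(c.position, c.wt_aa, c.mut_aa, label))
    return records
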