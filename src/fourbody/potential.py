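"""The four-body statistical potential.

For every quadruplet composition (an unordered multiset of four amino-acid
types; 8855 exist over the 20 standard types), the potential compares the
observed normalized frequency ``f`` of that composition among all Delaunay
simplices of a training corpus against the rate ``p`` expected by chance
under a multinomial reference distribution,

    p = c * prod_r a_r ** t_r,      c = 4! / prod_r t_r!,

where ``a_r`` is the corpus-wide normalized frequency of amino-acid type
``r`` and ``t_r`` its multiplicity in the quadruplet.  The log-likelihood
score ``q = log(f / p)`` (inverse Boltzmann form) is positive for
compositions that cluster together more often than chance and negative for
avoided ones.

Zero-count compositions have no defined ``log f``; the table records the
policy used to score them (add-one pseudocount by default, or a flat floor
score).  Compositions containing a type never seen in the corpus have
``p = 0`` and carry no information; they are scored 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

from .structures import AA_ALPHABET, CAlphaTrace
from .tessellation import Tessellation, quadruplet_composition

__all__ = [
    "QuadrupletStats",
    "PotentialTable",
    "enumerate_quadruplet_keys",
    "permutation_factor",
    "count_quadruplets",
    "expected_rate",
    "train_potential",
]

QuadrupletKey = tuple[str, str, str, str]


def enumerate_quadruplet_keys(alphabet: str = AA_ALPHABET) -> list[QuadrupletKey]:
    """All size-4 multisets over ``alphabet``, lexicographically ordered.

    Over the 20 standard amino acids this yields C(23, 4) = 8855 keys.
    """
    return list(combinations_with_replacement(sorted(alphabet), 4))


def permutation_factor(key: QuadrupletKey) -> int:
    """c = 4! / prod(t_r!) — distinct orderings of the composition."""
    c = math.factorial(4)
    for t in Counter(key).values():
        c //= math.factorial(t)
    return c


def expected_rate(key: QuadrupletKey, aa_freq: dict[str, float]) -> float:
    """Multinomial chance rate p = c * prod a_r^{t_r} for one composition.

    Raises
    ------
    ValueError
        If any type in the key has zero (or missing) corpus frequency —
        the rate is then undefined for scoring purposes.
    """
    p = float(permutation_factor(key))
    for aa, t in Counter(key).items():
        a = aa_freq.get(aa, 0.0)
        if a <= 0.0:
            raise ValueError(f"amino-acid type {aa!r} has zero corpus frequency")
        p *= a**t
    return p


def count_quadruplets(
    corpus: Iterable[tuple[Tessellation, CAlphaTrace]],
) -> tuple[Counter, Counter]:
    """Aggregate quadruplet and amino-acid counts over a corpus.

    Quadruplet counts run over all simplices of all tessellations;
    amino-acid counts run over all residues of all traces.
    """
    quad_counts: Counter = Counter()
    aa_counts: Counter = Counter()
    n = 0
    for tess, trace in corpus:
        n += 1
        for s in tess.simplices:
            quad_counts[quadruplet_composition(tess, trace, s)] += 1
        aa_counts.update(r.aa for r in trace.residues)
    if n == 0:
        raise ValueError("empty corpus")
    return quad_counts, aa_counts


@dataclass(frozen=True)
class QuadrupletStats:
    """Frequency statistics and score for one quadruplet composition."""

    observed_count: int
    f: float  # observed normalized frequency (0 for unobserved keys)
    p: float  # expected multinomial rate (0 if a type is absent)
    q: float  # log-likelihood score in the table's log base


@dataclass
class PotentialTable:
    """A trained four-body potential: one entry per each of the 8855 keys."""

    stats: dict[QuadrupletKey, QuadrupletStats]
    aa_freq: dict[str, float]
    total_quadruplets: int
    log_base: float = 10.0
    unobserved_policy: str = "pseudocount"

    def score(self, key: Sequence[str]) -> float:
        """q for a composition given in any order."""
        k = tuple(sorted(key))
        return self.stats[k].q  # type: ignore[index]

    def to_text(self) -> str:
        """Serialize sorted by key; retraining is byte-stable."""
        lines = [
            f"# log_base {self.log_base}",
            f"# total_quadruplets {self.total_quadruplets}",
            f"# unobserved_policy {self.unobserved_policy}",
            "# aa_freq " + " ".join(
                f"{aa}:{self.aa_freq.get(aa, 0.0):.12g}" for aa in AA_ALPHABET
            ),
        ]
        for key in sorted(self.stats):
            s = self.stats[key]
            lines.append(
                f"{''.join(key)} {s.observed_count} {s.f:.12g} {s.p:.12g} {s.q:.12g}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PotentialTable":
        log_base = 10.0
        total = 0
        policy = "pseudocount"
        aa_freq: dict[str, float] = {}
        stats: dict[QuadrupletKey, QuadrupletStats] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[0] == "log_base":
                    log_base = float(parts[1])
                elif parts[0] == "total_quadruplets":
                    total = int(parts[1])
                elif parts[0] == "unobserved_policy":
                    policy = parts[1]
                elif parts[0] == "aa_freq":
                    for item in parts[1:]:
                        aa, v = item.split(":")
                        aa_freq[aa] = float(v)
                continue
            keystr, obs, f, p, q = line.split()
            key = (keystr[0], keystr[1], keystr[2], keystr[3])
            stats[key] = QuadrupletStats(int(obs), float(f), float(p), float(q))
        return cls(stats, aa_freq, total, log_base, policy)


def train_potential(
    corpus: Iterable[tuple[Tessellation, CAlphaTrace]],
    log_base: float = 10.0,
    unobserved_policy: str = "pseudocount",
    floor_score: float | None = None,
    aa_pseudocount: float = 0.0,
) -> PotentialTable:
    """Derive the four-body potential from a tessellated corpus.

    Parameters
    ----------
    corpus
        Pairs of (tessellation, trace); must contain at least one simplex.
    log_base
        Base of the logarithm in ``q`` (rescales all scores uniformly).
    unobserved_policy
        How zero-count keys are scored.  ``"pseudocount"`` (default):
        q = log(f1 / p) with f1 the add-one smoothed frequency
        1 / (total + 8855).  ``"floor"``: q = ``floor_score`` (or the
        minimum observed q if ``floor_score`` is None).
    floor_score
        Flat score for the ``"floor"`` policy.
    aa_pseudocount
        Optional pseudocount added to every amino-acid count before
        normalizing ``a_r``; 0 keeps the raw corpus frequencies (types
        absent from the corpus then have a_r = 0 and their keys score 0).

    Notes
    -----
    Stored ``f`` values are the raw observed normalized frequencies
    (count / total), which sum to 1 over the observed keys; smoothing only
    enters the ``q`` of unobserved keys.
    """
    if unobserved_policy not in ("pseudocount", "floor"):
        raise ValueError(f"unknown unobserved_policy {unobserved_policy!r}")
    quad_counts, aa_counts = count_quadruplets(corpus)
    total = sum(quad_counts.values())
    if total == 0:
        raise ValueError("corpus contains no simplices (cutoff too strict?)")

    total_res = sum(aa_counts.values()) + aa_pseudocount * len(AA_ALPHABET)
    aa_freq = {
        aa: (aa_counts.get(aa, 0) + aa_pseudocount) / total_res for aa in AA_ALPHABET
    }

    keys = enumerate_quadruplet_keys()
    n_keys = len(keys)
    log_b = math.log(log_base)
    stats: dict[QuadrupletKey, QuadrupletStats] = {}
    observed_q: list[float] = []
    pending_unobserved: list[tuple[QuadrupletKey, float, float]] = []

    for key in keys:
        count = quad_counts.get(key, 0)
        f = count / total
        try:
            p = expected_rate(key, aa_freq)
        except ValueError:
            p = 0.0
        if count > 0:
            if p == 0.0:  # impossible: an observed key's types all have a_r > 0
                raise AssertionError("observed key with zero expected rate")
            q = math.log(f / p) / log_b
            observed_q.append(q)
            stats[key] = QuadrupletStats(count, f, p, q)
        else:
            pending_unobserved.append((key, f, p))

    floor = floor_score if floor_score is not None else (
        min(observed_q) if observed_q else 0.0
    )
    f1 = 1.0 / (total + n_keys)  # add-one smoothed frequency for zero counts
    for key, f, p in pending_unobserved:
        if p == 0.0:
            q = 0.0  # composition contains a type never seen in the corpus
        elif unobserved_policy == "pseudocount":
            q = math.log(f1 / p) / log_b
        else:
            q = floor
        stats[key] = QuadrupletStats(0, f, p, q)

    return PotentialTable(
        stats=stats,
        aa_freq=aa_freq,
        total_quadruplets=total,
        log_base=log_base,
        unobserved_policy=unobserved_policy,
    )
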