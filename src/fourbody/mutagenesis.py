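"""Computational mutagenesis: potential profiles and residual profiles.

Each residue's *environment score* is the sum of the four-body potential
scores ``q`` of every simplex it participates in; the vector of environment
scores over a chain is the *potential profile*.  A single-site mutant is
represented on the frozen wild-type tessellation by relabeling one vertex
and recomputing scores — only simplices incident to the mutated point
change.  The *residual profile* (mutant minus wild-type profile) is
therefore sparse: its nonzero entries, the environmental-change (EC)
scores, sit exactly at the mutated position and its tessellation nearest
neighbors.  Residual profiles are the feature vectors fed to the activity
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import AA_ALPHABET, CAlphaTrace
from .tessellation import Tessellation
from .potential import PotentialTable

__all__ = [
    "MutantRecord",
    "PotentialProfile",
    "ResidualProfile",
    "residue_environment_scores",
    "mutant_profile",
    "residual_profile",
    "feature_matrix",
    "all_single_site_mutations",
    "read_mutant_list",
    "write_mutant_list",
    "write_feature_matrix",
    "read_feature_matrix",
]

#: Label codes: active, inactive, unlabeled.
ACTIVE, INACTIVE, UNLABELED = 1, -1, 0


@dataclass(frozen=True)
class MutantRecord:
    """A single-site substitution with an optional binary activity label.

    ``activity`` is +1 (active), -1 (inactive) or 0 (unlabeled).
    """

    position: int
    wt_aa: str
    mut_aa: str
    activity: int = UNLABELED

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_ALPHABET or self.mut_aa not in AA_ALPHABET:
            raise ValueError("amino-acid types must be standard one-letter codes")
        if self.mut_aa == self.wt_aa:
            raise ValueError("mutant type must differ from wild type")
        if self.activity not in (ACTIVE, INACTIVE, UNLABELED):
            raise ValueError("activity must be +1, -1 or 0 (unlabeled)")

    def validate_against(self, trace: CAlphaTrace) -> None:
        if not 1 <= self.position <= len(trace):
            raise ValueError(f"position {self.position} outside 1..{len(trace)}")
        actual = trace.residues[self.position - 1].aa
        if actual != self.wt_aa:
            raise ValueError(
                f"wild-type mismatch at position {self.position}: trace has "
                f"{actual}, record says {self.wt_aa}"
            )


@dataclass
class PotentialProfile:
    """Vector of residue environment scores; source is ``"wt"`` or
    ``(position, mut_aa)``."""

    scores: np.ndarray
    source: object = "wt"


@dataclass
class ResidualProfile:
    """EC-score vector (mutant profile minus wild-type profile)."""

    ec_scores: np.ndarray
    mutant: MutantRecord


def residue_environment_scores(
    tess: Tessellation, labels: "list[str] | str", table: PotentialTable
) -> PotentialProfile:
    """Sum q over the simplices incident to each position.

    ``labels`` is the amino-acid type per position (length ``n_points``);
    positions participating in no simplex score 0.
    """
    labels = list(labels)
    if len(labels) != tess.n_points:
        raise ValueError("labels length must equal the tessellated point count")
    for aa in labels:
        if aa not in AA_ALPHABET:
            raise ValueError(f"nonstandard amino-acid label {aa!r}")
    scores = np.zeros(tess.n_points)
    for s in tess.simplices:
        q = table.score([labels[v - 1] for v in s.vertices])
        for v in s.vertices:
            scores[v - 1] += q
    return PotentialProfile(scores=scores)


def _delta_scores(
    tess: Tessellation,
    labels: list[str],
    table: PotentialTable,
    position: int,
    mut_aa: str,
) -> np.ndarray:
    """Change in environment scores caused by relabeling one vertex.

    Only simplices having the mutated point as a vertex change their q;
    the delta is accumulated on each of their four vertices.
    """
    delta = np.zeros(tess.n_points)
    for s in tess.incidence().get(position, []):
        old_key = [labels[v - 1] for v in s.vertices]
        new_key = [mut_aa if v == position else labels[v - 1] for v in s.vertices]
        dq = table.score(new_key) - table.score(old_key)
        for v in s.vertices:
            delta[v - 1] += dq
    return delta


def mutant_profile(
    tess: Tessellation,
    trace: CAlphaTrace,
    table: PotentialTable,
    mutation: MutantRecord,
) -> PotentialProfile:
    """Potential profile of a mutant on the frozen wild-type tessellation.

    Equivalent to :func:`residue_environment_scores` after substituting the
    amino-acid label at the mutated vertex; the geometry is not recomputed.
    """
    mutation.validate_against(trace)
    labels = [r.aa for r in trace.residues]
    wt = residue_environment_scores(tess, labels, table)
    delta = _delta_scores(tess, labels, table, mutation.position, mutation.mut_aa)
    return PotentialProfile(
        scores=wt.scores + delta, source=(mutation.position, mutation.mut_aa)
    )


def residual_profile(
    wt: PotentialProfile, mut: PotentialProfile, mutation: MutantRecord
) -> ResidualProfile:
    """EC scores: componentwise mutant minus wild-type profile."""
    if wt.scores.shape != mut.scores.shape:
        raise ValueError("profile length mismatch")
    return ResidualProfile(ec_scores=mut.scores - wt.scores, mutant=mutation)


def feature_matrix(
    trace: CAlphaTrace,
    tess: Tessellation,
    table: PotentialTable,
    mutants: "list[MutantRecord]",
) -> tuple[np.ndarray, np.ndarray]:
    """Residual profiles for a batch of mutants, one row each.

    Returns ``(X, y)`` where ``X`` is ``(len(mutants), N)`` and ``y`` the
    +1/-1/0 label vector in input order.  Feature vectors keep full length N
    (zeros included) so the classifier input dimension is constant across
    mutants.  An invalid mutant fails the whole batch with its index.
    """
    labels = [r.aa for r in trace.residues]
    X = np.zeros((len(mutants), len(trace)))
    y = np.zeros(len(mutants), dtype=int)
    for i, m in enumerate(mutants):
        try:
            m.validate_against(trace)
        except ValueError as exc:
            raise ValueError(f"mutant #{i}: {exc}") from exc
        X[i] = _delta_scores(tess, labels, table, m.position, m.mut_aa)
        y[i] = m.activity
    return X, y


def all_single_site_mutations(trace: CAlphaTrace) -> list[MutantRecord]:
    """Every possible single-site substitution: 19 per position, 19N total."""
    out = []
    for r in trace.residues:
        for aa in AA_ALPHABET:
            if aa != r.aa:
                out.append(MutantRecord(r.seq_index, r.aa, aa))
    return out


# ---------------------------------------------------------------------------
# delimited-text interfaces


def read_mutant_list(text: str) -> list[MutantRecord]:
    """Parse lines of ``position wt_aa mut_aa label`` (label +1/-1/?)."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 fields, got {len(parts)}")
        pos_s, wt, mut, label_s = parts
        if label_s == "?":
            label = UNLABELED
        elif label_s in ("+1", "1"):
            label = ACTIVE
        elif label_s == "-1":
            label = INACTIVE
        else:
            raise ValueError(f"line {lineno}: label must be +1, -1 or ?")
        try:
            out.append(MutantRecord(int(pos_s), wt, mut, label))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return out


def write_mutant_list(mutants: "list[MutantRecord]") -> str:
    lines = ["# position wt_aa mut_aa label"]
    for m in mutants:
        label = {ACTIVE: "+1", INACTIVE: "-1", UNLABELED: "?"}[m.activity]
        lines.append(f"{m.position} {m.wt_aa} {m.mut_aa} {label}")
    return "\n".join(lines) + "\n"


def write_feature_matrix(
    X: np.ndarray, mutants: "list[MutantRecord]", source_id: str = ""
) -> str:
    """One row per mutant: ``position wt mut label ec_1 .. ec_N``."""
    n = X.shape[1] if X.size else 0
    lines = [
        f"# source {source_id}",
        f"# columns position wt_aa mut_aa label ec_1..ec_{n}",
    ]
    for row, m in zip(X, mutants):
        label = {ACTIVE: "+1", INACTIVE: "-1", UNLABELED: "?"}[m.activity]
        lines.append(
            f"{m.position} {m.wt_aa} {m.mut_aa} {label} "
            + " ".join(f"{v:.10g}" for v in row)
        )
    return "\n".join(lines) + "\n"


def read_feature_matrix(text: str) -> tuple[np.ndarray, "list[MutantRecord]"]:
    rows = []
    mutants = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        pos, wt, mut, label_s = parts[:4]
        label = {"?": UNLABELED, "+1": ACTIVE, "1": ACTIVE, "-1": INACTIVE}[label_s]
        mutants.append(MutantRecord(int(pos), wt, mut, label))
        rows.append([float(v) for v in parts[4:]])
    X = np.array(rows) if rows else np.zeros((0, 0))
    return X, mutants
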