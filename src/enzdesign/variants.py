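"""Variant nomenclature, candidate enumeration, PAM30 clustering, selection.

Variants are sets of point substitutions against a reference sequence,
written as hyphenated tokens (``L48F-S49A-…``).  An alias table lets named
base variants compose (``V1-K352I`` replaces V1's substitution at 352 with
the net change from the original reference).  Candidate variants carry an
evidence score (lower is better); PAM30-derived distances feed deterministic
average-linkage clustering, from which the lowest-scored representative of
each cluster is selected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from enzdesign.alphabet import AA20
from enzdesign.errors import InputError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class Substitution:
    """A point substitution at a 1-based position."""

    position: int
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        if self.from_residue == self.to_residue:
            raise ValidationError(f"substitution at {self.position} has from == to")
        for res in (self.from_residue, self.to_residue):
            if res not in AA20:
                raise ValidationError(f"non-standard residue {res!r} at {self.position}")
        if self.position < 1:
            raise ValidationError("positions are 1-based")

    def token(self) -> str:
        return f"{self.from_residue}{self.position}{self.to_residue}"


@dataclass
class Variant:
    """A named set of substitutions relative to a base sequence."""

    base_id: str
    substitutions: tuple[Substitution, ...]
    display_name: str = ""
    provenance: frozenset[str] = frozenset()
    score: float = 0.0
    burial_class: str = ""
    pocket: bool = False

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions, key=lambda s: s.position))
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"duplicate positions in variant: {positions}")
        self.substitutions = subs
        if not self.display_name:
            self.display_name = self.name

    @property
    def name(self) -> str:
        """Canonical hyphenated net form, sorted by position."""
        return "-".join(s.token() for s in self.substitutions) if self.substitutions else "WT"

    def residue_at(self, position: int, base: str) -> str:
        for s in self.substitutions:
            if s.position == position:
                return s.to_residue
        return base[position - 1]


def _validate_against_base(subs: dict[int, Substitution], base: str) -> None:
    for pos, sub in subs.items():
        if pos > len(base):
            raise ValidationError(f"position {pos} beyond base length {len(base)}")
        if base[pos - 1] != sub.from_residue:
            raise ValidationError(
                f"position {pos}: from-residue {sub.from_residue} does not match "
                f"base residue {base[pos - 1]}"
            )


def _compose(
    current: dict[int, Substitution], tokens: list[str], base: str
) -> dict[int, Substitution]:
    """Apply substitution tokens on top of an existing substitution map.

    The from-residue of each token must match the current sequence (base with
    ``current`` applied); the stored net from-residue always comes from the
    original base.  A token restoring the base residue removes the entry.
    """
    out = dict(current)
    for tok in tokens:
        m = _TOKEN_RE.match(tok)
        if m is None:
            raise ValidationError(f"bad substitution token {tok!r}")
        frm, pos, to = m.group(1), int(m.group(2)), m.group(3)
        if frm == to:
            raise ValidationError(f"substitution {tok} has from == to")
        if pos < 1 or pos > len(base):
            raise ValidationError(f"position {pos} outside base of length {len(base)}")
        current_res = out[pos].to_residue if pos in out else base[pos - 1]
        if frm != current_res:
            raise ValidationError(
                f"position {pos}: token {tok} expects {frm} but sequence has {current_res}"
            )
        net_from = base[pos - 1]
        if to == net_from:
            out.pop(pos, None)  # restored to base: no net substitution
        else:
            out[pos] = Substitution(pos, net_from, to)
    return out


def parse_variant_name(
    name: str,
    base: str,
    aliases: dict[str, "Variant"] | None = None,
) -> Variant:
    """Parse a hyphenated variant name against a base sequence.

    Tokens match ``[A-Z]\\d+[A-Z]``.  An optional leading alias (resolved via
    ``aliases``) composes: later tokens at an already-substituted position
    replace it, with the net from-residue taken from the original base.
    """
    aliases = aliases or {}
    parts = [p for p in name.split("-") if p]
    if not parts:
        raise ValidationError("empty variant name")
    subs: dict[int, Substitution] = {}
    display = name
    start = 0
    if parts[0] in aliases:
        base_variant = aliases[parts[0]]
        subs = {s.position: s for s in base_variant.substitutions}
        _validate_against_base(subs, base)
        start = 1
    elif not _TOKEN_RE.match(parts[0]):
        raise ValidationError(f"unknown alias or bad token {parts[0]!r}")
    subs = _compose(subs, parts[start:], base)
    return Variant(base_id="base", substitutions=tuple(subs.values()), display_name=display)


def apply_variant(v: Variant, base: str) -> str:
    """Base sequence with the variant's substitutions applied."""
    subs = {s.position: s for s in v.substitutions}
    _validate_against_base(subs, base)
    seq = list(base)
    for pos, sub in subs.items():
        seq[pos - 1] = sub.to_residue
    return "".join(seq)


def diff_sequences(base: str, mutant: str) -> tuple[Substitution, ...]:
    """Substitution set turning ``base`` into ``mutant`` (equal lengths)."""
    if len(base) != len(mutant):
        raise InputError("sequences differ in length")
    return tuple(
        Substitution(i + 1, b, m) for i, (b, m) in enumerate(zip(base, mutant)) if b != m
    )


def combine_substitutions(
    base_variant: Variant,
    beneficial: list[Substitution],
    base: str,
) -> Variant:
    """Compose beneficial substitutions onto a base variant.

    Each beneficial substitution is validated against the sequence the base
    variant produces; replacement semantics at occupied positions recompute
    the net from-residue against the original base.  The display name is the
    base variant's display name with the new tokens appended.
    """
    subs = {s.position: s for s in base_variant.substitutions}
    _validate_against_base(subs, base)
    tokens = [s.token() for s in beneficial]
    combined = _compose(subs, tokens, base)
    display = "-".join([base_variant.display_name] + tokens) if tokens else base_variant.display_name
    return Variant(
        base_id=base_variant.base_id,
        substitutions=tuple(combined.values()),
        display_name=display,
        provenance=base_variant.provenance | {"manual"} if tokens else base_variant.provenance,
    )


# ---------------------------------------------------------------------------
# candidate enumeration


@dataclass
class VariantSet:
    """Candidate variants plus their pairwise distance matrix (lazy)."""

    base: str
    variants: list[Variant]
    distance_matrix: np.ndarray | None = None


def enumerate_candidates(
    base: str,
    pssm_subs: list,
    coev_subs: list,
    env_by_residue: dict[int, object] | None = None,
    env_filter: str = "all",
) -> VariantSet:
    """One single-substitution candidate per evidence record.

    ``pssm_subs`` are ``(position, from, to, score)`` records and
    ``coev_subs`` are ``(position, from, to, partner, gain)`` records; a
    substitution proposed by both streams is a single variant with merged
    provenance.  Score is ``-(PSSM gain) - (coupling gain)`` (missing terms
    0, lower is better).  ``env_filter`` restricts to ``surface`` /
    ``pocket`` / ``all`` using the supplied residue environments.
    """
    if env_filter not in ("all", "surface", "pocket"):
        raise ParameterError(f"unknown filter {env_filter!r}")
    env_by_residue = env_by_residue or {}
    merged: dict[tuple[int, str, str], dict] = {}
    for rec in pssm_subs:
        pos, frm, to, score = rec.position, rec.from_residue, rec.to_residue, rec.score
        entry = merged.setdefault((pos, frm, to), {"pssm": 0.0, "coev": 0.0, "prov": set()})
        entry["pssm"] = max(entry["pssm"], float(score))
        entry["prov"].add("pssm")
    for rec in coev_subs:
        pos, frm, to, gain = rec.position, rec.from_residue, rec.to_residue, rec.coupling_gain
        entry = merged.setdefault((pos, frm, to), {"pssm": 0.0, "coev": 0.0, "prov": set()})
        entry["coev"] = max(entry["coev"], float(gain))
        entry["prov"].add("coevolution")

    variants: list[Variant] = []
    for (pos, frm, to), entry in sorted(merged.items()):
        env = env_by_residue.get(pos)
        burial = getattr(env, "burial_class", "unknown")
        pocket = bool(getattr(env, "pocket", False))
        if env is None:
            logger.warning("no environment data for position %d; class set to unknown", pos)
        if env_filter == "surface" and burial != "surface":
            continue
        if env_filter == "pocket" and not pocket:
            continue
        variants.append(
            Variant(
                base_id="base",
                substitutions=(Substitution(pos, frm, to),),
                provenance=frozenset(entry["prov"]),
                score=-(entry["pssm"]) - (entry["coev"]),
                burial_class=burial,
                pocket=pocket,
            )
        )
    return VariantSet(base=base, variants=variants)


# ---------------------------------------------------------------------------
# PAM30 distances and clustering


def load_pam30() -> dict[tuple[str, str], float]:
    """NCBI PAM30 similarity table as a symmetric dict over residue pairs."""
    mat = substitution_matrices.load("PAM30")
    table: dict[tuple[str, str], float] = {}
    for a in AA20:
        for b in AA20:
            table[(a, b)] = float(mat[a, b])
    return table


def variant_distance(
    a: Variant,
    b: Variant,
    base: str,
    similarity: dict[tuple[str, str], float] | None = None,
) -> float:
    """PAM30-derived distance over the union of mutated positions.

    With ``x`` = a's residue and ``y`` = b's residue at each such position::

        d = sum (s(x, x) + s(y, y) - 2 s(x, y)) / 2

    Zero for identical variants, symmetric by construction.
    """
    sim = similarity if similarity is not None else load_pam30()
    positions = sorted(
        {s.position for s in a.substitutions} | {s.position for s in b.substitutions}
    )
    total = 0.0
    for pos in positions:
        x = a.residue_at(pos, base)
        y = b.residue_at(pos, base)
        total += (sim[(x, x)] + sim[(y, y)] - 2.0 * sim[(x, y)]) / 2.0
    return total


def distance_matrix(vs: VariantSet, similarity: dict | None = None) -> np.ndarray:
    sim = similarity if similarity is not None else load_pam30()
    n = len(vs.variants)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = variant_distance(vs.variants[i], vs.variants[j], vs.base, sim)
    vs.distance_matrix = D
    return D


@dataclass
class ClusterAssignment:
    variant_set: VariantSet
    k: int
    labels: np.ndarray  # 1..k per variant

    def members(self, label: int) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == label]


def _average_linkage(D: np.ndarray, k: int) -> list[frozenset[int]]:
    """Naive deterministic average-linkage agglomeration down to k clusters.

    Cluster-cluster distance is the unweighted mean over member pairs; ties
    in the merge choice are broken by the smallest (cluster-id, cluster-id)
    pair where ids are the clusters' smallest original member indices.
    """
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(D))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pts_a, pts_b = sorted(clusters[a]), sorted(clusters[b])
                d = float(np.mean([D[i, j] for i in pts_a for j in pts_b]))
                ids = tuple(sorted((min(clusters[a]), min(clusters[b]))))
                cand = (d, ids, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
    return sorted(clusters, key=min)


def cluster_variants(vs: VariantSet, k: int = 8) -> ClusterAssignment:
    """Cut deterministic average-linkage clustering of the PAM30 distances at k."""
    n = len(vs.variants)
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, {n}]")
    D = vs.distance_matrix if vs.distance_matrix is not None else distance_matrix(vs)
    clusters = _average_linkage(D, k)
    labels = np.zeros(n, dtype=int)
    for label, members in enumerate(clusters, start=1):
        for i in members:
            labels[i] = label
    return ClusterAssignment(variant_set=vs, k=k, labels=labels)


def select_representatives(ca: ClusterAssignment) -> list[Variant]:
    """Lowest-scored variant per cluster; ties by canonical-name order."""
    reps: list[Variant] = []
    for label in range(1, ca.k + 1):
        members = [ca.variant_set.variants[i] for i in ca.members(label)]
        reps.append(min(members, key=lambda v: (v.score, v.name)))
    return reps


def write_variant_report(
    vs: VariantSet,
    ca: ClusterAssignment | None,
    representatives: list[Variant] | None,
    path: str,
) -> None:
    """TSV report: name, substitutions, provenance, environment, score, cluster."""
    rep_names = {v.name for v in representatives} if representatives else set()
    with open(path, "w") as fh:
        fh.write("name\tsubstitutions\tprovenance\tburial_class\tpocket\tscore\tcluster\trepresentative\n")
        for idx, v in enumerate(vs.variants):
            label = int(ca.labels[idx]) if ca is not None else 0
            fh.write(
                f"{v.display_name}\t{v.name}\t{'+'.join(sorted(v.provenance)) or '-'}\t"
                f"{v.burial_class or 'unknown'}\t{int(v.pocket)}\t{v.score:.6f}\t"
                f"{label}\t{int(v.name in rep_names)}\n"
            )
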