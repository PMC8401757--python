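"""Statistical-parsimony (TCS-style) haplotype networks for the SSU V4 region.

Identical V4 sequences collapse into haplotypes that keep their samples'
habitat/geography metadata.  Haplotypes are then connected into a network
of single-mutation edges: components are grown by joining the closest
pairs first, inserting inferred median (unsampled intermediate) nodes so
every edge spans exactly one mutational step, and never joining across
more steps than the statistical-parsimony connection limit.

The connection limit is the largest step count *j* for which the estimated
probability that *j* observed differences arose without any superimposed
(homoplasious) change still reaches the chosen confidence (95% by
default), following the statistical-parsimony criterion of Templeton,
Crandall & Sing (1992) as popularized by the TCS program (Clement et al.
2000).  The estimator used here treats substitutions as Poisson hits per
site under a Jukes-Cantor model; the exact formula is given in
:func:`parsimony_probability`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io_formats import MetadataRecord, SequenceRecord
from .cbc_barcode import AnalysisConfig


class NetworkError(ValueError):
    pass


@dataclass
class Haplotype:
    """A distinct V4 sequence variant with its member samples."""

    id: str
    sequence: str  # ungapped
    members: list[tuple[str, MetadataRecord | None]] = field(default_factory=list)
    aligned: str | None = None  # original aligned row, when inputs carried gaps

    @property
    def multiplicity(self) -> int:
        return len(self.members)

    def habitat_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, md in self.members:
            key = md.habitat if md is not None else "unknown"
            out[key] = out.get(key, 0) + 1
        return out

    def geography_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, md in self.members:
            key = (md.geography or "unknown") if md is not None else "unknown"
            out[key] = out.get(key, 0) + 1
        return out


@dataclass
class HaplotypeNetwork:
    """Unit-step haplotype graph with inferred median nodes."""

    graph: nx.Graph
    haplotypes: dict[str, Haplotype]
    limit: int

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def total_steps(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in sorted(self.graph.nodes(data=True)):
            hap = self.haplotypes.get(node)
            rows.append({
                "id": node,
                "kind": data.get("kind", "median"),
                "multiplicity": hap.multiplicity if hap else 0,
                "habitats": ";".join(f"{k}:{v}" for k, v in
                                     sorted(hap.habitat_counts().items()))
                            if hap else "",
                "geographies": ";".join(f"{k}:{v}" for k, v in
                                        sorted(hap.geography_counts().items()))
                               if hap else "",
                "species": ";".join(sorted({md.species_label
                                            for _, md in hap.members
                                            if md and md.species_label}))
                           if hap else "",
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Collapsing

def collapse_haplotypes(seqs: list[SequenceRecord],
                        metadata: list[MetadataRecord] | None = None
                        ) -> list[Haplotype]:
    """Merge identical sequences into haplotypes; multiplicity is conserved.

    Sequences must share one ungapped length (aligned inputs are compared
    as aligned rows so indel states are preserved).  Metadata rows are
    matched to sequences by strain ID.
    """
    if not seqs:
        raise NetworkError("no sequences given")
    md_by_strain = {m.strain: m for m in (metadata or [])}
    lengths = {len(s.ungapped()) for s in seqs}
    aligned_lengths = {len(s.sequence) for s in seqs}
    if len(aligned_lengths) != 1:
        if len(lengths) != 1:
            raise NetworkError(
                f"ungapped lengths differ: {sorted(lengths)}")
        raise NetworkError(
            f"sequences are not aligned to one length: {sorted(aligned_lengths)}")
    groups: dict[str, Haplotype] = {}
    order: list[str] = []
    for s in seqs:
        key = s.sequence
        if key not in groups:
            groups[key] = Haplotype(id="", sequence=s.ungapped(), aligned=key)
            order.append(key)
        groups[key].members.append((s.id, md_by_strain.get(s.id)))
    haps = [groups[k] for k in order]
    haps.sort(key=lambda h: (-h.multiplicity, h.aligned))
    for i, h in enumerate(haps, start=1):
        h.id = f"H{i:02d}"
    return haps


def rename_haplotypes(haps: list[Haplotype], mapping: dict[str, str]) -> None:
    """Apply a user naming scheme (e.g. the D-1a style of published figures)."""
    for h in haps:
        h.id = mapping.get(h.id, h.id)


# ---------------------------------------------------------------------------
# Distances

def mutational_steps(a: str, b: str) -> int:
    """Hamming-style step count; a contiguous gap run counts one step."""
    if len(a) != len(b):
        raise NetworkError("sequences must have equal (aligned) length")
    steps = 0
    in_gap_run = False
    for ca, cb in zip(a, b):
        if ca == cb:
            in_gap_run = False
            continue
        if ca == "-" or cb == "-":
            if not in_gap_run:
                steps += 1
            in_gap_run = True
        else:
            steps += 1
            in_gap_run = False
    return steps


# ---------------------------------------------------------------------------
# Statistical-parsimony limit

def parsimony_probability(j: int, seq_length: int) -> float:
    """Probability that ``j`` observed differences over ``seq_length``
    sites arose without superimposed change (no homoplasy).

    Substitutions hit each site as a Poisson process with mean ``lam``
    solved from the Jukes-Cantor relation ``j/m = 3/4 (1 - exp(-4 lam /3))``;
    a site observed identical was parsimonious iff it had zero hits, a site
    observed different iff it had exactly one.  In log space::

        log P = (m - j) * [ -lam - log(1/4 + 3/4 exp(-4 lam/3)) ]
              +      j  * [ log(lam) - lam - log(p) ]

    with ``p = j/m``.  P is 1 at j=0 and decreases in j.
    """
    m = seq_length
    if m <= 0:
        raise NetworkError("seq_length must be positive")
    if j == 0:
        return 1.0
    p = j / m
    if p >= 0.75:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    log_ident = -lam - math.log(0.25 + 0.75 * math.exp(-4.0 * lam / 3.0))
    log_diff = math.log(lam) - lam - math.log(p)
    return math.exp((m - j) * log_ident + j * log_diff)


def parsimony_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest step count connectable at the given confidence (>= 1).

    Single steps are always considered connectable, so the limit is floored
    at 1 even at confidence 1.0.  The limit is non-decreasing in
    ``seq_length`` at fixed confidence.
    """
    if seq_length <= 0:
        raise NetworkError("seq_length must be positive")
    if not 0 < confidence <= 1:
        raise NetworkError("confidence must be in (0, 1]")
    j = 1
    while j < seq_length and \
            parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# Network construction

def _intermediates(a: str, b: str) -> list[str]:
    """Unit-step path from a to b, mutating differing positions left to
    right; gap runs switch in one step. Returns the strict intermediates."""
    out = []
    cur = list(a)
    diff_events: list[list[int]] = []
    in_gap_run = False
    for pos, (ca, cb) in enumerate(zip(a, b)):
        if ca == cb:
            in_gap_run = False
            continue
        if ca == "-" or cb == "-":
            if in_gap_run:
                diff_events[-1].append(pos)
            else:
                diff_events.append([pos])
            in_gap_run = True
        else:
            diff_events.append([pos])
            in_gap_run = False
    for event in diff_events[:-1]:
        for pos in event:
            cur[pos] = b[pos]
        out.append("".join(cur))
    return out


def build_network(haps: list[Haplotype], limit: int) -> HaplotypeNetwork:
    """Grow the network by joining closest components first.

    Haplotype pairs are visited in order of increasing step distance (ties:
    higher multiplicity, then lexicographic ID); a pair in different
    components at distance <= ``limit`` is connected by a fresh path of
    median nodes so that every edge spans one step.  Pairs beyond the limit
    stay in separate components, which are therefore maximal under the
    limit.  Total edge count equals the minimum-spanning step total.
    """
    if limit < 1:
        raise NetworkError("limit must be >= 1")
    g = nx.Graph()
    hap_map = {h.id: h for h in haps}
    seqs = {h.id: (h.aligned if h.aligned is not None else h.sequence)
            for h in haps}
    for h in haps:
        g.add_node(h.id, kind="observed", multiplicity=h.multiplicity,
                   sequence=seqs[h.id])
    pairs = []
    for a, b in itertools.combinations(sorted(hap_map), 2):
        d = mutational_steps(seqs[a], seqs[b])
        key = (d,
               -max(hap_map[a].multiplicity, hap_map[b].multiplicity),
               -min(hap_map[a].multiplicity, hap_map[b].multiplicity),
               a, b)
        pairs.append((key, a, b, d))
    pairs.sort(key=lambda t: t[0])

    median_count = 0
    for _, a, b, d in pairs:
        if d == 0 or d > limit:
            continue
        if nx.has_path(g, a, b):
            continue
        path = [a]
        for inter_seq in _intermediates(seqs[a], seqs[b]):
            median_count += 1
            mid = f"med{median_count:02d}"
            g.add_node(mid, kind="median", multiplicity=0,
                       sequence=inter_seq)
            path.append(mid)
        path.append(b)
        for u, v in zip(path, path[1:]):
            g.add_edge(u, v)
    return HaplotypeNetwork(g, hap_map, limit)


# ---------------------------------------------------------------------------
# Query assignment

@dataclass(frozen=True)
class Assignment:
    species: str | None
    haplotype: str | None
    identity: float
    coverage: float

    @property
    def assigned(self) -> bool:
        return self.species is not None


def _best_ungapped_match(query: str, ref: str) -> tuple[float, float]:
    """(identity, coverage) of the best ungapped sliding alignment.

    Coverage is the aligned span over the reference (V4 region) length;
    identity is matches over the aligned span.
    """
    q, r = query.replace("-", ""), ref.replace("-", "")
    if not q or not r:
        return 0.0, 0.0
    short, long_ = (q, r) if len(q) <= len(r) else (r, q)
    span = len(short)
    best = 0
    for off in range(len(long_) - span + 1):
        matches = sum(1 for x, y in zip(short, long_[off:off + span]) if x == y)
        best = max(best, matches)
    coverage = span / len(r)
    identity = best / span
    return identity, coverage


def assign_query(query: SequenceRecord, references: list[Haplotype],
                 config: AnalysisConfig | None = None) -> Assignment:
    """Assign an environmental sequence to a species by identity/coverage.

    The query is accepted only when its best ungapped match covers the full
    reference region (coverage >= ``coverage_required``) with identity
    strictly above ``identity_min`` (the defaults reproduce the
    100%-coverage / >97%-identity acceptance rule).
    """
    if not references:
        raise NetworkError("no reference haplotypes")
    config = config or AnalysisConfig()
    best: tuple[float, float, Haplotype] | None = None
    for hap in references:
        ident, cov = _best_ungapped_match(query.sequence, hap.sequence)
        cand = (ident, cov, hap)
        if best is None or (ident, cov) > (best[0], best[1]):
            best = cand
    ident, cov, hap = best
    if cov >= config.coverage_required and ident > config.identity_min:
        species = sorted({md.species_label for _, md in hap.members
                         if md and md.species_label})
        return Assignment(species[0] if species else hap.id, hap.id,
                          ident, cov)
    return Assignment(None, None, ident, cov)
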