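"""Base-paired ITS-2 structures, three-helix annotation and conserved columns.

The ITS-2 of the algae handled here folds into three helices (I-III; helix
IV is absent).  Only the terminal loops of helices I and II vary between
strains, so the species-diagnostic signal sits in the base pairs of the
conserved core.  This module represents structures (from dot-bracket
input), decomposes them into stems labelled I/II/III in 5'->3' order, and
selects the alignment columns that are paired consistently in every strain
of a set -- the columns the number-code barcode is read from.

Coordinates are 0-based internally; reports use 1-based inclusive positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io_formats import FormatError, SequenceRecord, make_record

#: Helix labels in 5'->3' order of the opening strand.
HELIX_LABELS = ("I", "II", "III")

#: Default terminal-loop exclusion: loops of helices I and II only.
DEFAULT_LOOP_EXCLUDE = ("I", "II")


class StructureError(ValueError):
    """Raised for invalid pairings or inconsistent structure sets."""


@dataclass(frozen=True)
class StructuredSequence:
    """An (aligned) RNA sequence with its base-pairing map and helix labels.

    ``pairing`` holds 0-based ``(i, j)`` tuples with ``i < j``; each
    position belongs to at most one pair and pairs are nested.
    ``helix_of_position`` labels positions ``"I"/"II"/"III"`` (paired stem
    positions), ``"loop:X"`` (terminal-loop positions of helix X) or
    ``"spacer"`` (everything else); it is empty until
    :func:`annotate_helices` has run.
    """

    record: SequenceRecord
    pairing: tuple[tuple[int, int], ...]
    helix_of_position: dict[int, str] = field(default_factory=dict)

    @property
    def partner(self) -> dict[int, int]:
        """Position -> paired partner (both directions)."""
        out: dict[int, int] = {}
        for i, j in self.pairing:
            out[i] = j
            out[j] = i
        return out

    def __len__(self) -> int:
        return len(self.record.sequence)


@dataclass(frozen=True)
class ConservedColumnSet:
    """Alignment columns paired in every strain of a set.

    ``alignment_columns`` lists every conserved column (both pair sides) in
    ascending order; ``pair_partner`` maps each to its partner and is an
    involution.  ``pair_columns`` gives the ``(open, close)`` pairs ordered
    5'->3' by the opening strand -- the order barcode columns are read in.
    """

    alignment_columns: tuple[int, ...]
    pair_partner: dict[int, int]

    @property
    def pair_columns(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(
            (c, p) for c, p in self.pair_partner.items() if c < p))

    def __len__(self) -> int:
        return len(self.alignment_columns)


def pairing_from_dotbracket(sequence: str, structure: str) -> StructuredSequence:
    """Convert a dot-bracket string into a :class:`StructuredSequence`.

    The pairing set matches bracket matching exactly; unbalanced input
    raises with the first offending index.
    """
    if len(sequence) != len(structure):
        raise StructureError(
            f"sequence length {len(sequence)} != structure length "
            f"{len(structure)}")
    rec = sequence if isinstance(sequence, SequenceRecord) else None
    if rec is None:
        rec = make_record("anonymous", sequence) if sequence else None
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at index {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(
                f"invalid structure character {ch!r} at index {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at index {stack[0]}")
    return StructuredSequence(rec, tuple(sorted(pairs)))


def structured_from_record(record: SequenceRecord,
                           structure: str) -> StructuredSequence:
    ss = pairing_from_dotbracket(record.sequence, structure)
    return StructuredSequence(record, ss.pairing)


def _stem_decomposition(pairing, max_bulge: int):
    """Group nested, nearly-stacked pairs into stems.

    Consecutive pairs extend one stem when nested and separated by at most
    ``max_bulge`` unpaired nucleotides on either strand.
    """
    stems: list[list[tuple[int, int]]] = []
    for i, j in sorted(pairing):
        if stems:
            pi, pj = stems[-1][-1]
            if (i > pi and j < pj
                    and i - pi - 1 <= max_bulge
                    and pj - j - 1 <= max_bulge):
                stems[-1].append((i, j))
                continue
        stems.append([(i, j)])
    return stems


def annotate_helices(ss: StructuredSequence, min_stem_len: int = 2,
                     max_bulge: int = 3) -> StructuredSequence:
    """Label the helices of an ITS-2 structure I, II, III in 5'->3' order.

    Stems shorter than ``min_stem_len`` stacked pairs are ignored (their
    positions stay "spacer").  More than three qualifying stems is an error
    (the three-helix model does not apply; supply a template override);
    fewer than three triggers a warning and labels the stems present.
    Terminal-loop positions (enclosed by a stem's innermost pair with no
    pairs inside) are labelled ``"loop:X"``.

    Annotation depends only on the pairing, never on sequence content.
    """
    stems = [s for s in _stem_decomposition(ss.pairing, max_bulge)
             if len(s) >= min_stem_len]
    if len(stems) > len(HELIX_LABELS):
        raise StructureError(
            f"{len(stems)} stems of >= {min_stem_len} pairs found; the "
            "three-helix ITS-2 model expects at most 3 (override the "
            "stem-length filter or supply a template)")
    if len(stems) < len(HELIX_LABELS):
        warnings.warn(
            f"only {len(stems)} helices found; labelling those present",
            stacklevel=2)
    stems.sort(key=lambda s: s[0][0])
    paired_positions = {p for i, j in ss.pairing for p in (i, j)}
    labels: dict[int, str] = {}
    for label, stem in zip(HELIX_LABELS, stems):
        for i, j in stem:
            labels[i] = label
            labels[j] = label
        inner_i, inner_j = stem[-1]
        inside = range(inner_i + 1, inner_j)
        if all(p not in paired_positions for p in inside):
            for p in inside:
                labels[p] = f"loop:{label}"
    for p in range(len(ss)):
        labels.setdefault(p, "spacer")
    return StructuredSequence(ss.record, ss.pairing, labels)


def transfer_pairing(reference: StructuredSequence,
                     records: list[SequenceRecord]) -> list[StructuredSequence]:
    """Homology option: impose a reference pairing on aligned strains.

    Each reference pair is transferred column-by-column; a pair is dropped
    for a strain that carries a gap on either side (the position is then
    effectively unpaired/deleted there).
    """
    ref_len = len(reference)
    out = []
    for rec in records:
        if len(rec.sequence) != ref_len:
            raise StructureError(
                f"strain {rec.id!r}: aligned length {len(rec.sequence)} != "
                f"reference length {ref_len}")
        pairs = tuple(
            (i, j) for i, j in reference.pairing
            if rec.sequence[i] != "-" and rec.sequence[j] != "-")
        out.append(StructuredSequence(rec, pairs, dict(reference.helix_of_position)))
    return out


def conserved_columns(strains: list[StructuredSequence],
                      exclude_loops_of=DEFAULT_LOOP_EXCLUDE) -> ConservedColumnSet:
    """Select alignment columns paired identically in every strain.

    Returns exactly the columns paired in all strains (barcode codes 1-7),
    minus any column sitting in a helix I/II terminal loop of some strain.
    Columns paired to different partners in different strains are an error
    (the structures are not homologous at those columns).
    """
    if not strains:
        raise StructureError("no strains given")
    lengths = {len(s) for s in strains}
    if len(lengths) != 1:
        raise StructureError(
            f"strains are not in one alignment (lengths {sorted(lengths)})")
    n = lengths.pop()
    partners = [s.partner for s in strains]
    loop_labels = {f"loop:{h}" for h in exclude_loops_of}
    conserved: list[int] = []
    partner_map: dict[int, int] = {}
    inconsistent: list[int] = []
    for c in range(n):
        vals = {p.get(c) for p in partners}
        if None in vals:
            continue  # unpaired in at least one strain
        if len(vals) > 1:
            inconsistent.append(c)
            continue
        if any(s.helix_of_position.get(c) in loop_labels for s in strains):
            continue
        conserved.append(c)
        partner_map[c] = vals.pop()
    if inconsistent:
        raise StructureError(
            "inconsistent pair partners across strains at columns "
            + ", ".join(str(c + 1) for c in inconsistent))
    # keep only columns whose partner also survived selection
    kept = [c for c in conserved if partner_map[c] in partner_map]
    partner_map = {c: partner_map[c] for c in kept}
    return ConservedColumnSet(tuple(kept), partner_map)
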