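"""SSU V4-region annotation against an E23 helix template and clade
diagnostics (NHS, CBC, HCBC).

The hypervariable V4 region of the 18S rRNA carries the helices named
E23_1 ... E23_14.  Given a template that places these helices on an
ungapped reference sequence, the region is sliced out of a full SSU
alignment, every column is labelled with a helix or inter-helix spacer,
and clade-diagnostic characters are collected:

* **NHS** (non-homoplasious synapomorphy): a column state shared by every
  clade member and absent from all strains outside the clade; when a tree
  is supplied, additionally required to originate once under parsimony.
* **CBC / HCBC**: a paired column where the clade's base pair differs from
  every outside pair, classified against the outside majority pair with
  the same change classes used for ITS-2 barcodes.

The packaged template (``data/synthetic_v4_template.tsv``) is a synthetic
stand-in that demonstrates the format; analyses of real strains should
supply a template with the coordinates of their own reference structure.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .cbc_barcode import ChangeClass, classify_change, encode_pair
from .io_formats import UNAMBIGUOUS, FormatError, SequenceRecord
from .lineage_tree import LineageTree


class TemplateError(ValueError):
    pass


@dataclass(frozen=True)
class V4Template:
    """Helix spans (1-based inclusive, on the ungapped reference) + pairing.

    Each span row is ``(helix, start, end, partner_helix)``; the two spans
    of one hairpin share the helix name (or name each other via
    ``partner_helix``) and pair antiparallel.
    """

    reference_id: str
    spans: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self):
        taken: list[tuple[int, int]] = []
        for helix, start, end, _ in self.spans:
            if start > end or start < 1:
                raise TemplateError(f"bad span for {helix}: {start}..{end}")
            for s, e in taken:
                if start <= e and end >= s:
                    raise TemplateError(
                        f"overlapping template spans at {helix}")
            taken.append((start, end))
        self.reference_pairing()  # validates strand pairing eagerly

    @property
    def region(self) -> tuple[int, int]:
        """1-based inclusive start/end of the whole V4 region."""
        return (min(s for _, s, _, _ in self.spans),
                max(e for _, _, e, _ in self.spans))

    def reference_pairing(self) -> list[tuple[int, int]]:
        """0-based reference position pairs implied by the spans."""
        by_key: dict[tuple[str, str], list[tuple[str, int, int, str]]] = {}
        for row in self.spans:
            helix, _, _, partner = row
            if not partner:
                continue
            key = tuple(sorted((helix, partner)))
            by_key.setdefault(key, []).append(row)
        pairs: list[tuple[int, int]] = []
        for key, rows in by_key.items():
            if len(rows) != 2:
                raise TemplateError(
                    f"helix pairing {key} needs exactly two spans, "
                    f"got {len(rows)}")
            rows.sort(key=lambda r: r[1])
            (_, s5, e5, _), (_, s3, e3, _) = rows
            if e5 - s5 != e3 - s3:
                raise TemplateError(
                    f"strand lengths differ for pairing {key}")
            for k in range(e5 - s5 + 1):
                pairs.append((s5 - 1 + k, e3 - 1 - k))
        return sorted(pairs)

    def helix_of_ref_position(self) -> dict[int, str]:
        """0-based reference position -> helix label (spans only)."""
        out = {}
        for helix, start, end, _ in self.spans:
            for p in range(start - 1, end):
                out[p] = helix
        return out


def load_template(path, reference_id: str) -> V4Template:
    """Read a template TSV (helix, start, end, partner_helix)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    required = {"helix", "start", "end", "partner_helix"}
    if not required <= set(df.columns):
        raise TemplateError(
            f"template needs columns {sorted(required)}")
    spans = tuple(
        (row.helix, int(row.start), int(row.end), row.partner_helix)
        for row in df.itertuples(index=False))
    return V4Template(reference_id, spans)


def packaged_template(reference_id: str = "SYNTHETIC_REF") -> V4Template:
    """The synthetic demonstration template shipped with the package."""
    ref = importlib.resources.files("phycodelim") / "data" / \
        "synthetic_v4_template.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_template(path, reference_id)


# ---------------------------------------------------------------------------
# Extraction and annotation

@dataclass(frozen=True)
class V4Slice:
    """Aligned V4 subsequences plus the reference coordinate map."""

    records: tuple[SequenceRecord, ...]
    template: V4Template
    column_offset: int  # first alignment column of the slice (0-based)
    ref_column_of_pos: dict[int, int]  # 0-based ref pos -> slice column


def _reference_column_map(ref_row: str) -> dict[int, int]:
    out, pos = {}, 0
    for col, ch in enumerate(ref_row):
        if ch != "-":
            out[pos] = col
            pos += 1
    return out


def extract_v4(ssu_alignment: list[SequenceRecord],
               template: V4Template) -> V4Slice:
    """Slice the V4 region out of a full SSU alignment.

    Template start/end (reference coordinates) are mapped through the
    reference row's gaps; every strain is sliced over the same columns, so
    internal gap characters are preserved.
    """
    ref = next((r for r in ssu_alignment if r.id == template.reference_id),
               None)
    if ref is None:
        raise TemplateError(
            f"reference {template.reference_id!r} absent from alignment")
    colmap = _reference_column_map(ref.sequence)
    start, end = template.region
    if end - 1 not in colmap:
        raise TemplateError(
            f"template region {start}..{end} exceeds the ungapped "
            f"reference length {len(colmap)}")
    c0, c1 = colmap[start - 1], colmap[end - 1]
    records = tuple(
        SequenceRecord(r.id, r.sequence[c0:c1 + 1], r.description)
        for r in ssu_alignment)
    slice_map = {pos: col - c0 for pos, col in colmap.items()
                 if c0 <= col <= c1}
    return V4Slice(records, template, c0, slice_map)


def annotate_v4(v4: V4Slice) -> tuple[list[str], list[tuple[int, int]]]:
    """Label every slice column and map the template pairing onto columns.

    Returns ``(labels, pairing)``: one label per column (a helix name or
    ``spacer(X-Y)`` between the flanking helices) and 0-based column pairs
    for the template's paired positions.
    """
    helix_of_pos = v4.template.helix_of_ref_position()
    n = len(v4.records[0].sequence)
    col_to_pos = {col: pos for pos, col in v4.ref_column_of_pos.items()}
    # (start column, end column, helix) for every template span, in order
    span_cols = sorted(
        (v4.ref_column_of_pos[start - 1], v4.ref_column_of_pos[end - 1], h)
        for h, start, end, _ in v4.template.spans
        if start - 1 in v4.ref_column_of_pos
        and end - 1 in v4.ref_column_of_pos)

    labels = []
    for col in range(n):
        pos = col_to_pos.get(col)
        if pos is not None and pos in helix_of_pos:
            labels.append(helix_of_pos[pos])
            continue
        left = next((h for s, e, h in reversed(span_cols) if e < col), "5'")
        right = next((h for s, e, h in span_cols if s > col), "3'")
        if left == right:
            labels.append(f"loop({left})")  # between a hairpin's two strands
        else:
            labels.append(f"spacer({left}-{right})")
    pairing = []
    for p5, p3 in v4.template.reference_pairing():
        c5 = v4.ref_column_of_pos.get(p5)
        c3 = v4.ref_column_of_pos.get(p3)
        if c5 is not None and c3 is not None:
            pairing.append((c5, c3))
    return labels, pairing


# ---------------------------------------------------------------------------
# Diagnostics

@dataclass(frozen=True)
class DiagnosticFeature:
    kind: str  # "NHS", "CBC" or "HCBC"
    location: tuple[int, ...]  # 1-based slice column(s)
    label: str
    clade_state: str
    outside_state: str
    clade: frozenset[str]
    autapomorphy: bool = False
    polymorphic_outside: bool = False


def _check_clade(records, clade):
    ids = {r.id for r in records}
    clade = frozenset(clade)
    if not clade:
        raise ValueError("empty clade")
    if not clade <= ids:
        raise ValueError(f"clade members not in alignment: "
                         f"{sorted(clade - ids)}")
    if clade == ids:
        raise ValueError("clade equals the full strain set")
    return clade


def _fitch_changes(tree: LineageTree, state_of_leaf: dict[str, int]) -> int:
    """Minimum state changes of a binary character on the tree (Fitch)."""
    changes = 0

    def post(node):
        nonlocal changes
        if node.is_leaf():
            return {state_of_leaf[node.taxon.label]}
        sets = [post(c) for c in node.child_nodes()]
        inter = set.intersection(*sets)
        if inter:
            return inter
        changes += len(sets) - 1 if len(sets) > 2 else 1
        return set.union(*sets)

    post(tree.tree.seed_node)
    return changes


def find_nhs(records: list[SequenceRecord], clade,
             tree: LineageTree | None = None,
             labels: list[str] | None = None,
             pairing: list[tuple[int, int]] | None = None
             ) -> list[DiagnosticFeature]:
    """Columns whose state is fixed in the clade and absent outside it.

    With a tree, candidate columns must additionally map to a single
    origin (one state change under Fitch parsimony).  A clade of size one
    yields autapomorphy-flagged features.  When ``pairing`` is given, the
    paired columns are skipped -- changes there belong to the CBC/HCBC
    classification of :func:`find_pair_synapomorphies`, not to the NHS
    count.
    """
    clade = _check_clade(records, clade)
    inside = [r for r in records if r.id in clade]
    outside = [r for r in records if r.id not in clade]
    paired_cols = {c for pr in (pairing or []) for c in pr}
    n = len(records[0].sequence)
    feats = []
    for col in range(n):
        if col in paired_cols:
            continue
        states_in = {r.sequence[col] for r in inside}
        if len(states_in) != 1:
            continue
        s = states_in.pop()
        if s == "-" or s not in UNAMBIGUOUS:
            continue
        if any(r.sequence[col] == s for r in outside):
            continue
        if tree is not None:
            leaf_state = {r.id: int(r.sequence[col] == s) for r in records}
            if _fitch_changes(tree, leaf_state) != 1:
                continue
        out_states = sorted({r.sequence[col] for r in outside})
        feats.append(DiagnosticFeature(
            kind="NHS",
            location=(col + 1,),
            label=labels[col] if labels else "",
            clade_state=s,
            outside_state="/".join(out_states),
            clade=clade,
            autapomorphy=len(clade) == 1,
        ))
    return feats


def find_pair_synapomorphies(records: list[SequenceRecord],
                             pairing: list[tuple[int, int]], clade,
                             labels: list[str] | None = None
                             ) -> list[DiagnosticFeature]:
    """Paired columns where the clade's base pair differs from all outside
    pairs, classified CBC/HCBC against the outside majority pair."""
    clade = _check_clade(records, clade)
    inside = [r for r in records if r.id in clade]
    outside = [r for r in records if r.id not in clade]
    feats = []
    for c5, c3 in pairing:
        pairs_in = {(r.sequence[c5], r.sequence[c3]) for r in inside}
        if len(pairs_in) != 1:
            continue
        pin = pairs_in.pop()
        pairs_out = [(r.sequence[c5], r.sequence[c3]) for r in outside]
        if pin in pairs_out:
            continue
        counts: dict[tuple[str, str], int] = {}
        for p in pairs_out:
            counts[p] = counts.get(p, 0) + 1
        majority = max(sorted(counts), key=lambda p: counts[p])
        polymorphic = len(counts) > 1
        try:
            cls = classify_change(encode_pair(*pin), encode_pair(*majority))
        except FormatError:
            continue
        if cls not in (ChangeClass.CBC, ChangeClass.HCBC):
            continue
        feats.append(DiagnosticFeature(
            kind="CBC" if cls is ChangeClass.CBC else "HCBC",
            location=(c5 + 1, c3 + 1),
            label=labels[c5] if labels else "",
            clade_state="-".join(pin),
            outside_state="-".join(majority),
            clade=clade,
            autapomorphy=len(clade) == 1,
            polymorphic_outside=polymorphic,
        ))
    return feats


def flag_singleton_mismatches(records: list[SequenceRecord],
                              pairing: list[tuple[int, int]]
                              ) -> list[tuple[str, int]]:
    """Flag strains whose private state breaks a pair -- suspected
    sequencing errors.  Returns ``(strain, 1-based column)`` tuples; the
    strains are flagged, never removed."""
    out = []
    for c5, c3 in pairing:
        for col, partner in ((c5, c3), (c3, c5)):
            states: dict[str, list[str]] = {}
            for r in records:
                states.setdefault(r.sequence[col], []).append(r.id)
            for state, who in states.items():
                if len(who) != 1:
                    continue
                r = next(rr for rr in records if rr.id == who[0])
                b5, b3 = r.sequence[c5], r.sequence[c3]
                if encode_pair(b5, b3).code == 7:
                    out.append((who[0], col + 1))
    return sorted(set(out))
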