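"""Number-code ITS-2 barcodes, CBC/HCBC classification and species delimitation.

Every conserved base pair is encoded on an 8-state scale::

    1 = A-U   2 = U-A   3 = G-C   4 = C-G   5 = G.U   6 = U.G
    7 = mismatch (any other two non-gap bases at a paired column)
    8 = deletion / single or unpaired base (a gap on either side)

Comparing two barcodes column-by-column yields, per column, one of:

* ``IDENTICAL``       -- same bases on both sides (gap-vs-gap included);
* ``CBC``             -- both strands changed, pairing retained (codes 1-6
  on both sides; e.g. A-U -> G-C);
* ``HCBC``            -- exactly one strand changed, pairing retained
  (e.g. A-U -> G.U);
* ``MISMATCH_CHANGE`` -- a mismatch (code 7) involved;
* ``INDEL_CHANGE``    -- a deletion/unpaired state (code 8) involved;
* ``AMBIGUOUS``       -- an IUPAC ambiguity code on either side; such
  columns are excluded from all counts and reported separately.

Species delimitation follows the CBC rule: lineages separated by at least
one CBC are distinct species regardless of tree support; lineages separated
only by HCBCs remain distinct species when both carry high lineage support
(bootstrap >= 70% or posterior >= 0.95 by default); otherwise they merge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

from .io_formats import RNA_ALPHABET, UNAMBIGUOUS, FormatError
from .its2_structure import ConservedColumnSet, StructuredSequence

#: The six pairing-retaining states (Watson-Crick + wobble), code 1-6.
PAIR_CODES = {
    ("A", "U"): 1,
    ("U", "A"): 2,
    ("G", "C"): 3,
    ("C", "G"): 4,
    ("G", "U"): 5,
    ("U", "G"): 6,
}

CODE_TO_PAIR = {v: k for k, v in PAIR_CODES.items()}

MISMATCH_CODE = 7
INDEL_CODE = 8


class ChangeClass(Enum):
    IDENTICAL = "identical"
    CBC = "CBC"
    HCBC = "hCBC"
    MISMATCH_CHANGE = "mismatch_change"
    INDEL_CHANGE = "indel_change"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BarcodeColumn:
    """One conserved pair: numeric code plus the underlying bases."""

    code: int
    base5: str
    base3: str

    def is_ambiguous(self) -> bool:
        ok = UNAMBIGUOUS | {"-"}
        return self.base5 not in ok or self.base3 not in ok


@dataclass(frozen=True)
class Barcode:
    """Per-strain vector of encoded conserved base pairs (5'->3' order)."""

    strain: str
    columns: tuple[BarcodeColumn, ...]

    def __len__(self) -> int:
        return len(self.columns)

    def code_string(self) -> str:
        """Render as concatenated digits, e.g. ``"3412..."``."""
        return "".join(str(c.code) for c in self.columns)


@dataclass(frozen=True)
class BarcodeComparison:
    strain_a: str
    strain_b: str
    per_column: tuple[ChangeClass, ...]
    n_cbc: int
    n_hcbc: int
    n_other: int

    @property
    def n_changes(self) -> int:
        return self.n_cbc + self.n_hcbc + self.n_other


@dataclass(frozen=True)
class AnalysisConfig:
    """Delimitation and assignment thresholds.

    ``bootstrap_support_min`` is a percentage, ``posterior_min`` a
    probability (used only when posterior values are supplied),
    ``identity_min`` and ``coverage_required`` are fractions for
    query assignment.
    """

    bootstrap_support_min: float = 70.0
    posterior_min: float = 0.95
    identity_min: float = 0.97
    coverage_required: float = 1.0

    def __post_init__(self):
        if not 0 <= self.bootstrap_support_min <= 100:
            raise ValueError("bootstrap_support_min must be in 0..100")
        for name in ("posterior_min", "identity_min", "coverage_required"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in 0..1")


@dataclass(frozen=True)
class Lineage:
    """A candidate species: a set of strains with optional edge support."""

    name: str
    strains: frozenset[str]
    bootstrap: float | None = None
    posterior: float | None = None


@dataclass(frozen=True)
class SpeciesPartition:
    """Delimited species with the evidence that keeps each split."""

    groups: tuple[tuple[str, ...], ...]
    evidence: dict
    config: AnalysisConfig

    @property
    def n_species(self) -> int:
        return len(self.groups)

    def species_of(self) -> dict[str, int]:
        return {s: i for i, grp in enumerate(self.groups) for s in grp}


# ---------------------------------------------------------------------------
# Encoding

def encode_pair(base5: str, base3: str, paired: bool = True) -> BarcodeColumn:
    """Encode one base pair on the 8-state scale (see module docstring)."""
    b5, b3 = base5.upper().replace("T", "U"), base3.upper().replace("T", "U")
    for b in (b5, b3):
        if b not in RNA_ALPHABET:
            raise FormatError(f"invalid nucleotide {b!r} in base pair")
    if not paired or b5 == "-" or b3 == "-":
        return BarcodeColumn(INDEL_CODE, b5, b3)
    code = PAIR_CODES.get((b5, b3), MISMATCH_CODE)
    return BarcodeColumn(code, b5, b3)


def encode_barcode(ss: StructuredSequence, cols: ConservedColumnSet) -> Barcode:
    """Read a strain's barcode over the conserved columns (5'->3')."""
    seq = ss.record.sequence
    partner = ss.partner
    columns = []
    for c_open, c_close in cols.pair_columns:
        if c_close >= len(seq):
            raise FormatError(
                f"strain {ss.record.id!r}: conserved column {c_close + 1} "
                "outside the aligned sequence")
        paired = partner.get(c_open) == c_close
        columns.append(encode_pair(seq[c_open], seq[c_close], paired=paired))
    return Barcode(ss.record.id, tuple(columns))


# ---------------------------------------------------------------------------
# Comparison

def classify_change(a: BarcodeColumn, b: BarcodeColumn) -> ChangeClass:
    """Classify the change between two encoded columns. Symmetric."""
    if a.base5 == b.base5 and a.base3 == b.base3:
        return ChangeClass.IDENTICAL
    if a.is_ambiguous() or b.is_ambiguous():
        return ChangeClass.AMBIGUOUS
    if (a.code == INDEL_CODE) != (b.code == INDEL_CODE):
        return ChangeClass.INDEL_CHANGE
    if a.code == INDEL_CODE and b.code == INDEL_CODE:
        # both carry a deletion/unpaired state but differ, e.g. (A,-) vs (-,U)
        return ChangeClass.INDEL_CHANGE
    if a.code == MISMATCH_CODE or b.code == MISMATCH_CODE:
        return ChangeClass.MISMATCH_CHANGE
    # both codes 1..6 from here on
    diff5 = a.base5 != b.base5
    diff3 = a.base3 != b.base3
    if diff5 and diff3:
        return ChangeClass.CBC
    return ChangeClass.HCBC


def compare_barcodes(a: Barcode, b: Barcode) -> BarcodeComparison:
    """Column-wise comparison of two equal-length barcodes. Symmetric."""
    if len(a) != len(b):
        raise ValueError(
            f"barcode length mismatch: {a.strain} has {len(a)} columns, "
            f"{b.strain} has {len(b)}")
    per_column = tuple(classify_change(ca, cb)
                       for ca, cb in zip(a.columns, b.columns))
    n_cbc = sum(c is ChangeClass.CBC for c in per_column)
    n_hcbc = sum(c is ChangeClass.HCBC for c in per_column)
    n_other = sum(c in (ChangeClass.MISMATCH_CHANGE, ChangeClass.INDEL_CHANGE)
                  for c in per_column)
    return BarcodeComparison(a.strain, b.strain, per_column,
                             n_cbc, n_hcbc, n_other)


def variable_positions(barcodes: list[Barcode]) -> tuple[list[int], list[int]]:
    """Split columns into variable and ambiguity-carrying sets.

    A column is variable when not all barcodes carry the same
    ``(base5, base3)`` -- base identity, not code identity, so two distinct
    mismatches (both code 7) still count as variable.  Columns with any
    IUPAC ambiguity are excluded from the variable set and listed apart.
    """
    if len(barcodes) < 2:
        raise ValueError("need at least two barcodes")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError(f"barcode lengths differ: {sorted(lengths)}")
    variable, ambiguous = [], []
    for k in range(lengths.pop()):
        cols = [b.columns[k] for b in barcodes]
        if any(c.is_ambiguous() for c in cols):
            ambiguous.append(k)
            continue
        if len({(c.base5, c.base3) for c in cols}) > 1:
            variable.append(k)
    return variable, ambiguous


def count_variable_positions(barcodes: list[Barcode]) -> int:
    """Number of base-pair positions at which the barcodes differ."""
    return len(variable_positions(barcodes)[0])


# ---------------------------------------------------------------------------
# Species delimitation

def _support_ok(lineage: Lineage, config: AnalysisConfig) -> bool:
    if lineage.bootstrap is not None and \
            lineage.bootstrap >= config.bootstrap_support_min:
        return True
    if lineage.posterior is not None and \
            lineage.posterior >= config.posterior_min:
        return True
    return False


def _separating_columns(group_a: list[Barcode], group_b: list[Barcode]):
    """Columns at which *every* cross-pair shows the same CBC/HCBC class."""
    n = len(group_a[0])
    cbc_cols, hcbc_cols = [], []
    for k in range(n):
        classes = {classify_change(a.columns[k], b.columns[k])
                   for a in group_a for b in group_b}
        if classes == {ChangeClass.CBC}:
            cbc_cols.append(k)
        elif classes == {ChangeClass.HCBC}:
            hcbc_cols.append(k)
    return cbc_cols, hcbc_cols


def delimit_species(lineages: list[Lineage], barcodes: list[Barcode],
                    config: AnalysisConfig | None = None) -> SpeciesPartition:
    """Merge or keep lineages according to the CBC/HCBC + support rule.

    Two lineages stay distinct species when separated by >= 1 CBC
    (regardless of support), or by >= 1 HCBC with both lineages supported
    above the configured thresholds.  Everything else (identical barcodes,
    or HCBC-only splits without support) merges by transitive closure.
    The result is invariant to strain and lineage ordering; groups are
    sorted by their lexicographically smallest strain ID.
    """
    config = config or AnalysisConfig()
    by_strain = {b.strain: b for b in barcodes}
    all_strains = [s for lin in lineages for s in lin.strains]
    if len(set(all_strains)) != len(all_strains):
        raise ValueError("lineages are not disjoint")
    for s in all_strains:
        if s not in by_strain:
            raise ValueError(f"strain {s!r} has no barcode")

    lineages = sorted(lineages, key=lambda l: min(l.strains))
    members = [sorted(l.strains) for l in lineages]
    bc_groups = [[by_strain[s] for s in m] for m in members]

    n = len(lineages)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    split_evidence = {}
    for i, j in itertools.combinations(range(n), 2):
        cbc_cols, hcbc_cols = _separating_columns(bc_groups[i], bc_groups[j])
        if cbc_cols:
            split_evidence[(lineages[i].name, lineages[j].name)] = {
                "kind": "CBC", "columns": [c + 1 for c in cbc_cols]}
        elif hcbc_cols and _support_ok(lineages[i], config) \
                and _support_ok(lineages[j], config):
            split_evidence[(lineages[i].name, lineages[j].name)] = {
                "kind": "HCBC+support", "columns": [c + 1 for c in hcbc_cols]}
        else:
            parent[find(i)] = find(j)

    groups_idx: dict[int, list[int]] = {}
    for i in range(n):
        groups_idx.setdefault(find(i), []).append(i)
    name_to_idx = {lin.name: i for i, lin in enumerate(lineages)}
    split_evidence = {
        pair: ev for pair, ev in split_evidence.items()
        if find(name_to_idx[pair[0]]) != find(name_to_idx[pair[1]])}
    groups = sorted(
        (tuple(sorted(s for i in idx for s in members[i]))
         for idx in groups_idx.values()),
        key=lambda g: g[0])
    return SpeciesPartition(tuple(groups), split_evidence, config)
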