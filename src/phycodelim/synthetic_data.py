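"""Synthetic ITS-2 structure sets and V4 alignments with planted ground truth.

The generators emulate the statistical structure of the study system --
coccoid green algae whose ITS-2 folds into three conserved helices with
variable helix I/II loops, and whose SSU V4 region separates species by a
handful of diagnostic positions -- while planting *exact* counts rather
than sampling them:

* ``generate_its2_dataset`` draws an ancestral barcode over codes 1-6 and
  derives each species by applying exactly the requested number of CBCs
  (both strands substituted, pairing kept) and hemi-CBCs (one strand,
  pairing kept) at globally disjoint conserved pairs.  Free variation is
  restricted to helix I/II terminal loops, so core counts are exact.
* ``generate_v4_dataset`` builds an E23-style helix template, gives every
  species a private set of diagnostic positions large enough that
  between-species distances exceed the statistical-parsimony connection
  limit, and strings within-species haplotypes along a known mutational
  chain.

A single integer seed governs all draws; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .cbc_barcode import CODE_TO_PAIR, PAIR_CODES, Lineage
from .haplotype_network import parsimony_limit
from .io_formats import MetadataRecord, SequenceRecord
from .its2_structure import StructuredSequence, annotate_helices, \
    pairing_from_dotbracket
from .v4_synapomorphy import V4Template


class ParameterError(ValueError):
    """Raised for infeasible generator parameter combinations."""


_SIX = list(PAIR_CODES)  # the six pairing-retaining base pairs

#: CBC moves: both strands differ, pairing retained.
_CBC_TARGETS = {p: [q for q in _SIX if q[0] != p[0] and q[1] != p[1]]
                for p in _SIX}
#: hemi-CBC moves: exactly one strand differs, pairing retained.
_HCBC_TARGETS = {p: [q for q in _SIX
                     if (q[0] != p[0]) != (q[1] != p[1])]
                 for p in _SIX}

_BASES = "ACGU"

_GEOGRAPHIES = ("North Sea", "Baltic Sea", "NE Atlantic", "SE Pacific",
                "Black Sea", "Atacama")

DEFAULT_HABITAT_MIX = {"marine": 0.6, "terrestrial": 0.3, "saline-soil": 0.1}


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    seed: int
    params: dict
    species_of: dict[str, str] = field(default_factory=dict)
    partition: tuple[tuple[str, ...], ...] = ()
    lineages: list[Lineage] = field(default_factory=list)
    # ITS-2 fields
    pair_changes: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    n_conserved_pairs: int = 0
    n_conserved_columns: int = 0
    n_variable_pairs: int = 0
    structure: str = ""
    # V4 fields
    haplotype_chains: dict[str, list[list[str]]] = field(default_factory=dict)
    nhs_columns: dict[str, list[int]] = field(default_factory=dict)
    pair_feature_columns: dict[str, list[tuple[str, tuple[int, int]]]] = field(default_factory=dict)
    connection_limit: int = 0
    v4_length: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["lineages"] = [
            {"name": l.name, "strains": sorted(l.strains),
             "bootstrap": l.bootstrap, "posterior": l.posterior}
            for l in self.lineages]
        d["pair_changes"] = {f"{a}|{b}": v
                             for (a, b), v in self.pair_changes.items()}
        return json.dumps(d, indent=1, default=list)


def _random_base(rng) -> str:
    return _BASES[rng.integers(0, 4)]


def _mutate_base(rng, base: str) -> str:
    others = [b for b in _BASES if b != base]
    return others[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# ITS-2

def generate_its2_dataset(n_species: int = 3, strains_per_species: int = 3,
                          core_width: int = 24, cbc_per_split: int = 1,
                          hcbc_per_split: int = 1,
                          loop_noise_rate: float = 0.1, seed: int = 0
                          ) -> tuple[list[StructuredSequence], SyntheticTruth]:
    """Aligned ITS-2 structures for ``n_species`` planted species.

    ``core_width`` counts conserved base *pairs*, split across the three
    helices.  Species ``SP1`` keeps the ancestral core; every further
    species applies ``cbc_per_split`` CBCs and ``hcbc_per_split`` hemi-CBCs
    at its own private pairs, so all planted counts are exact.  Loop noise
    (helix I/II terminal loops only) never touches paired columns.
    """
    if n_species < 1 or strains_per_species < 1:
        raise ParameterError("n_species and strains_per_species must be >= 1")
    if cbc_per_split < 0 or hcbc_per_split < 0:
        raise ParameterError("planted change counts must be >= 0")
    if core_width < cbc_per_split + hcbc_per_split:
        raise ParameterError("core_width must cover the planted changes")
    if core_width < 6:
        raise ParameterError("core_width must be >= 6 (two pairs per helix)")
    per_split = cbc_per_split + hcbc_per_split
    if (n_species - 1) * per_split > core_width:
        raise ParameterError(
            f"cannot plant {(n_species - 1) * per_split} disjoint changes "
            f"in a core of {core_width} pairs")

    rng = np.random.default_rng(seed)
    base, rem = divmod(core_width, 3)
    helix_pairs = [base + (1 if h < rem else 0) for h in range(3)]

    # layout: lead 2 | (open loop4 close) x3 with 3-nt spacers | tail 2
    loop_len, spacer_len = 4, 3
    structure_parts, pair_list, loop_positions = [], [], []
    pos = 0
    structure_parts.append("." * 2)
    pos += 2
    for h, p in enumerate(helix_pairs):
        open_start = pos
        close_start = pos + p + loop_len
        structure_parts.append("(" * p + "." * loop_len + ")" * p)
        for k in range(p):
            pair_list.append((open_start + k, close_start + p - 1 - k))
        if h < 2:  # loops of helices I and II are the variable ones
            loop_positions.extend(range(open_start + p, open_start + p + loop_len))
        pos = close_start + p
        if h < 2:
            structure_parts.append("." * spacer_len)
            pos += spacer_len
    structure_parts.append("." * 2)
    pos += 2
    structure = "".join(structure_parts)
    length = pos
    pair_list.sort()

    # ancestral sequence
    seq = [None] * length
    for i, j in pair_list:
        b5, b3 = _SIX[rng.integers(0, 6)]
        seq[i], seq[j] = b5, b3
    for i in range(length):
        if seq[i] is None:
            seq[i] = _random_base(rng)
    ancestor = seq

    species = [f"SP{k + 1}" for k in range(n_species)]
    pool = list(rng.permutation(core_width))
    species_core: dict[str, list[str]] = {}
    planted: dict[str, tuple[int, int]] = {}
    for k, sp in enumerate(species):
        row = list(ancestor)
        if k > 0:
            take_cbc = [pool.pop() for _ in range(cbc_per_split)]
            take_hcbc = [pool.pop() for _ in range(hcbc_per_split)]
            for idx in take_cbc:
                i, j = pair_list[idx]
                cur = (row[i], row[j])
                tgt = _CBC_TARGETS[cur][rng.integers(0, len(_CBC_TARGETS[cur]))]
                row[i], row[j] = tgt
            for idx in take_hcbc:
                i, j = pair_list[idx]
                cur = (row[i], row[j])
                tgt = _HCBC_TARGETS[cur][rng.integers(0, len(_HCBC_TARGETS[cur]))]
                row[i], row[j] = tgt
            planted[sp] = (cbc_per_split, hcbc_per_split)
        else:
            planted[sp] = (0, 0)
        species_core[sp] = row

    strains: list[StructuredSequence] = []
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_species=n_species, strains_per_species=strains_per_species,
                    core_width=core_width, cbc_per_split=cbc_per_split,
                    hcbc_per_split=hcbc_per_split,
                    loop_noise_rate=loop_noise_rate),
        structure=structure,
        n_conserved_pairs=core_width,
        n_conserved_columns=2 * core_width,
        n_variable_pairs=sum(c + h for c, h in planted.values()),
    )
    for sp in species:
        members = []
        for s in range(strains_per_species):
            row = list(species_core[sp])
            for lp in loop_positions:
                if rng.random() < loop_noise_rate:
                    row[lp] = _mutate_base(rng, row[lp])
            name = f"{sp}_s{s + 1}"
            rec = SequenceRecord(name, "".join(row),
                                 f"synthetic ITS-2 seed={seed}")
            ss = pairing_from_dotbracket(rec.sequence, structure)
            strains.append(annotate_helices(
                StructuredSequence(rec, ss.pairing)))
            members.append(name)
            truth.species_of[name] = sp
        truth.lineages.append(Lineage(sp, frozenset(members), bootstrap=99.0))
    truth.partition = tuple(sorted(
        tuple(sorted(l.strains)) for l in truth.lineages))
    for a in range(n_species):
        for b in range(a + 1, n_species):
            ca, ha = planted[species[a]]
            cb, hb = planted[species[b]]
            truth.pair_changes[(species[a], species[b])] = (ca + cb, ha + hb)
    return strains, truth


# ---------------------------------------------------------------------------
# V4

_V4_HELICES = ("E23_1", "E23_2", "E23_4", "E23_7", "E23_9", "E23_13")


def generate_v4_dataset(n_species: int = 3, haplotypes_per_species: int = 2,
                        steps_between: int = 1, samples_per_haplotype: int = 2,
                        habitat_mix: dict[str, float] | None = None,
                        seed: int = 0, n_nhs_per_species: int = 1,
                        n_cbc_pairs_per_species: int = 1,
                        n_hcbc_pairs_per_species: int = 1,
                        flank: int = 20
                        ) -> tuple[list[SequenceRecord], list[MetadataRecord],
                                   V4Template, SyntheticTruth]:
    """A synthetic SSU alignment whose V4 slice carries planted diagnostics.

    Every species receives private diagnostic positions (clade-fixed,
    absent outside: the planted NHSs), private helix pair changes (the
    planted CBC/HCBC features) and enough extra private substitutions that
    all between-species distances exceed the 95% statistical-parsimony
    connection limit.  Within a species, haplotypes form a chain whose
    consecutive members differ by exactly ``steps_between`` single
    substitutions at fresh positions.

    Returns ``(alignment, metadata, template, truth)``; the alignment
    contains one extra ``REF`` row (the ancestral sequence) that serves as
    the template reference and carries no sample metadata.
    """
    if min(n_species, haplotypes_per_species, samples_per_haplotype) < 1:
        raise ParameterError("counts must be >= 1")
    if steps_between < 1:
        raise ParameterError("steps_between must be >= 1")
    habitat_mix = dict(habitat_mix or DEFAULT_HABITAT_MIX)
    if abs(sum(habitat_mix.values()) - 1.0) > 1e-6:
        raise ParameterError("habitat_mix probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    stem, loop_len, spacer_len, lead = 5, 4, 4, 6
    n_pairs_total = stem * len(_V4_HELICES)
    pairs_needed = n_species * (n_cbc_pairs_per_species
                                + n_hcbc_pairs_per_species)
    if pairs_needed > n_pairs_total:
        raise ParameterError(
            f"{pairs_needed} planted pair features exceed the "
            f"{n_pairs_total} template stem pairs")

    # core layout (without tail)
    base_len = lead + len(_V4_HELICES) * (2 * stem + loop_len + spacer_len)

    # iterate tail size until the connection limit is self-consistent
    chain_total = n_species * (haplotypes_per_species - 1) * steps_between
    tail = 4
    for _ in range(20):
        length = base_len + tail
        limit = parsimony_limit(length)
        d = limit // 2 + 1  # private diffs per species => pair sums > limit
        div = max(0, d - n_nhs_per_species - 2 * n_cbc_pairs_per_species
                  - n_hcbc_pairs_per_species) if n_species > 1 else 0
        need = n_species * (n_nhs_per_species + div) + chain_total + 4
        if base_len + need <= length:
            break
        tail = need
    else:
        raise ParameterError("tail size did not converge")

    # build template + ancestral sequence
    spans: list[tuple[str, int, int, str]] = []
    pair_list: list[tuple[int, int]] = []
    seq: list[str] = []
    pos = lead
    seq.extend(_random_base(rng) for _ in range(lead))
    for helix in _V4_HELICES:
        open_start, close_start = pos, pos + stem + loop_len
        spans.append((helix, flank + open_start + 1,
                      flank + open_start + stem, helix))
        spans.append((helix, flank + close_start + 1,
                      flank + close_start + stem, helix))
        for k in range(stem):
            pair_list.append((open_start + k, close_start + stem - 1 - k))
        seq.extend([""] * (2 * stem + loop_len))
        for i, j in pair_list[-stem:]:
            seq[i], seq[j] = _SIX[rng.integers(0, 6)]
        for p in range(open_start + stem, open_start + stem + loop_len):
            seq[p] = _random_base(rng)
        pos = close_start + stem
        seq.extend(_random_base(rng) for _ in range(spacer_len))
        pos += spacer_len
    seq.extend(_random_base(rng) for _ in range(length - len(seq)))
    ancestor = list(seq)
    # the region spans the whole synthetic V4 core including the tail
    spans.append(("V4_tail", flank + base_len - spacer_len + 1,
                  flank + length, ""))

    template = V4Template("REF", tuple(spans))

    species = [f"SP{k + 1}" for k in range(n_species)]
    free_pool = [p for p in range(length)
                 if all(p not in pr for pr in pair_list)
                 ][::-1]  # unpaired positions, deterministic order
    free_pool = [p for p in free_pool if p >= lead]  # keep the lead conserved
    rng.shuffle(free_pool)
    stem_pool = list(rng.permutation(len(pair_list)))

    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_species=n_species,
                    haplotypes_per_species=haplotypes_per_species,
                    steps_between=steps_between,
                    samples_per_haplotype=samples_per_haplotype,
                    habitat_mix=habitat_mix,
                    n_nhs_per_species=n_nhs_per_species,
                    n_cbc_pairs_per_species=n_cbc_pairs_per_species,
                    n_hcbc_pairs_per_species=n_hcbc_pairs_per_species),
        connection_limit=limit,
        v4_length=length,
    )

    # truth coordinates are 0-based columns of the extracted V4 slice,
    # which starts at the first helix (core position `lead`)
    species_base: dict[str, list[str]] = {}
    for sp in species:
        row = list(ancestor)
        nhs_cols: list[int] = []
        if n_species > 1:
            for _ in range(n_nhs_per_species + div):
                p = free_pool.pop()
                row[p] = _mutate_base(rng, row[p])
                nhs_cols.append(p - lead)
            feats = []
            for _ in range(n_cbc_pairs_per_species):
                i, j = pair_list[stem_pool.pop()]
                cur = (row[i], row[j])
                tgt = _CBC_TARGETS[cur][rng.integers(0, len(_CBC_TARGETS[cur]))]
                row[i], row[j] = tgt
                feats.append(("CBC", (i - lead, j - lead)))
            for _ in range(n_hcbc_pairs_per_species):
                i, j = pair_list[stem_pool.pop()]
                cur = (row[i], row[j])
                tgt = _HCBC_TARGETS[cur][rng.integers(0, len(_HCBC_TARGETS[cur]))]
                row[i], row[j] = tgt
                feats.append(("HCBC", (i - lead, j - lead)))
            truth.pair_feature_columns[sp] = feats
        else:
            truth.pair_feature_columns[sp] = []
        truth.nhs_columns[sp] = sorted(nhs_cols)
        species_base[sp] = row

    habitats = sorted(habitat_mix)
    probs = [habitat_mix[h] for h in habitats]
    flank5 = "".join(_random_base(rng) for _ in range(flank))
    flank3 = "".join(_random_base(rng) for _ in range(flank))

    alignment = [SequenceRecord(
        "REF", flank5 + "".join(ancestor) + flank3,
        f"synthetic SSU reference seed={seed}")]
    metadata: list[MetadataRecord] = []
    for sp in species:
        row = list(species_base[sp])
        chains: list[list[str]] = []
        for t in range(haplotypes_per_species):
            if t > 0:
                for _ in range(steps_between):
                    p = free_pool.pop()
                    row[p] = _mutate_base(rng, row[p])
            hap_members = []
            for r in range(samples_per_haplotype):
                name = f"{sp}_h{t + 1}_r{r + 1}"
                alignment.append(SequenceRecord(
                    name, flank5 + "".join(row) + flank3,
                    f"synthetic V4 sample seed={seed}"))
                habitat = habitats[int(rng.choice(len(habitats), p=probs))]
                geography = _GEOGRAPHIES[rng.integers(0, len(_GEOGRAPHIES))]
                metadata.append(MetadataRecord(
                    strain=name, species_label=sp, origin="synthetic",
                    habitat=habitat, geography=geography))
                hap_members.append(name)
                truth.species_of[name] = sp
            chains.append(hap_members)
        truth.haplotype_chains[sp] = chains
        truth.lineages.append(Lineage(
            sp, frozenset(m for c in chains for m in c), bootstrap=99.0))
    truth.partition = tuple(sorted(
        tuple(sorted(l.strains)) for l in truth.lineages))
    return alignment, metadata, template, truth
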