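"""WRKY domain detection, heptapeptide variant census and group classification.

A WRKY domain is defined by two motifs: the WRKYGQK heptapeptide (the W is
invariant, the other six positions tolerate a small number of substitutions
— WRKYGKK being the classic variant) and, downstream of it, a zinc finger
of one of two kinds::

    C2H2:  C-X(4,5)-C-X(22,23)-H-X-H
    C2HC:  C-X(7)-C-X(23)-H-X-C

Proteins are assigned to the classical groups by domain count and
zinc-finger type: two valid domains -> group I (N- and C-terminal domain),
one valid C2H2 domain -> group II (subgroups IIa-IIe by nearest labeled
reference), one valid C2HC domain -> group III, three or more -> the rare
multi-domain architecture.  Sequences whose candidate domains lack either
motif are excluded from the family, mirroring genome-annotation practice.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import ProteinRecord

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: (zf_type, x1 choices, x2 choices, last residue) tried in order at each start.
_ZF_PATTERNS = (
    ("C2H2", (4, 5), (22, 23), "H"),
    ("C2HC", (7,), (23,), "C"),
)

SUBGROUP_LABELS = ("IIa", "IIb", "IIc", "IId", "IIe")


@dataclass(frozen=True)
class ZincFinger:
    zf_type: str              # "C2H2" | "C2HC"
    spacers: tuple[int, int]  # (x1, x2)
    span: tuple[int, int]     # half-open over the protein


@dataclass
class WrkyDomain:
    """One detected (candidate) WRKY domain."""

    protein_id: str
    heptapeptide: str
    hepta_start: int
    n_mismatches: int
    zf_type: str = "absent"
    zf_spacers: tuple[int, int] | None = None
    span: tuple[int, int] = (0, 0)
    valid: bool = False

    @property
    def is_canonical(self) -> bool:
        return self.heptapeptide == CANONICAL_HEPTAPEPTIDE


@dataclass
class WrkyAnnotation:
    """Per-protein classification call with its domain inventory."""

    protein_id: str
    species: str
    domains: list[WrkyDomain]
    n_valid_domains: int
    group: str                      # I | II | III | multi_domain | unclassified
    subgroup: str = "none"          # IIa..IIe | IIm | none
    subgroup_score: float = float("nan")
    subgroup_tie: bool = False
    terminal_labels: tuple[str, ...] = ()


@dataclass
class ReferenceSet:
    """Labeled reference domain sequences anchoring the group II subgroups."""

    references: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("reference set is empty")
        for label, seqs in self.references.items():
            if not seqs:
                raise ValueError(f"subgroup label {label!r} has no reference")


def find_heptapeptide_seeds(
    protein: ProteinRecord | str,
    max_mismatch: int = 2,
) -> list[tuple[int, str]]:
    """Scan for heptapeptide seeds within a mismatch budget of WRKYGQK.

    Position 1 (the W) must match exactly.  Overlapping candidate windows
    are resolved in favour of the fewest mismatches, then leftmost; the
    surviving seeds are returned left to right.
    """
    if not 0 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be in 0..3")
    seq = protein.seq if isinstance(protein, ProteinRecord) else protein
    seq = seq.upper()
    candidates: list[tuple[int, int]] = []  # (mismatches, offset)
    for off in range(len(seq) - 6):
        window = seq[off : off + 7]
        if window[0] != "W":
            continue
        mism = sum(a != b for a, b in zip(window[1:], CANONICAL_HEPTAPEPTIDE[1:]))
        if mism <= max_mismatch:
            candidates.append((mism, off))
    chosen: list[tuple[int, str]] = []
    taken: list[int] = []
    for mism, off in sorted(candidates):
        if any(abs(off - t) < 7 for t in taken):
            continue
        taken.append(off)
        chosen.append((off, seq[off : off + 7]))
    chosen.sort()
    return chosen


def find_zinc_finger(
    protein: ProteinRecord | str,
    from_offset: int,
    window: int = 120,
) -> ZincFinger | None:
    """Find the leftmost zinc-finger motif starting in the search window.

    At equal start position C2H2 is tried before C2HC, and within a pattern
    smaller spacers are tried first, so the leftmost-ending complete match
    wins.  Returns ``None`` when no pattern fits.
    """
    seq = protein.seq if isinstance(protein, ProteinRecord) else protein
    seq = seq.upper()
    limit = min(len(seq), from_offset + window)
    for start in range(max(from_offset, 0), limit):
        if seq[start] != "C":
            continue
        for zf_type, x1s, x2s, last in _ZF_PATTERNS:
            for x1 in x1s:
                c2 = start + 1 + x1
                if c2 >= len(seq) or seq[c2] != "C":
                    continue
                for x2 in x2s:
                    h1 = c2 + 1 + x2
                    end = h1 + 3  # H, X, last
                    if end > len(seq):
                        continue
                    if seq[h1] == "H" and seq[h1 + 2] == last:
                        return ZincFinger(zf_type, (x1, x2), (start, end))
    return None


def validate_and_assemble(
    protein: ProteinRecord,
    seeds: Sequence[tuple[int, str]] | None = None,
    max_mismatch: int = 2,
    window: int = 120,
) -> list[WrkyDomain]:
    """Pair heptapeptide seeds with downstream zinc fingers into domains.

    Each seed claims the nearest downstream zinc finger not already claimed
    by an earlier (more N-terminal) seed.  Seeds left without a zinc finger
    yield ``valid=False`` domains, which are reported but excluded from
    classification — proteins that lost either motif fall out of the family.
    """
    if seeds is None:
        seeds = find_heptapeptide_seeds(protein, max_mismatch=max_mismatch)
    claimed: list[tuple[int, int]] = []
    domains: list[WrkyDomain] = []
    for off, hepta in seeds:
        mism = sum(
            a != b for a, b in zip(hepta[1:], CANONICAL_HEPTAPEPTIDE[1:])
        )
        seed_end = off + 7
        from_off = seed_end
        hit = None
        while True:
            remaining = window - (from_off - seed_end)
            if remaining <= 0:
                hit = None
                break
            hit = find_zinc_finger(protein, from_off, window=remaining)
            if hit is None or hit.span not in claimed:
                break
            from_off = hit.span[0] + 1
        if hit is None:
            domains.append(
                WrkyDomain(protein.id, hepta, off, mism, "absent", None,
                           (off, seed_end), valid=False)
            )
        else:
            claimed.append(hit.span)
            domains.append(
                WrkyDomain(protein.id, hepta, off, mism, hit.zf_type,
                           hit.spacers, (off, hit.span[1]), valid=True)
            )
    return domains


def census_variants(
    domains: Iterable[WrkyDomain],
) -> tuple[pd.DataFrame, Counter]:
    """Tally heptapeptide composition across valid domains.

    Returns a 7 x 20 per-position amino-acid count table (rows are the
    heptapeptide positions 1..7) and a multiset of the non-canonical
    heptapeptide strings observed — the word-cloud data.
    """
    counts = pd.DataFrame(
        0, index=range(1, 8), columns=list(AMINO_ACIDS), dtype=int
    )
    tally: Counter = Counter()
    for dom in domains:
        if not dom.valid:
            continue
        for pos, aa in enumerate(dom.heptapeptide, start=1):
            if aa in counts.columns:
                counts.loc[pos, aa] += 1
        if not dom.is_canonical:
            tally[dom.heptapeptide] += 1
    counts.index.name = "position"
    return counts, tally


def assign_group(
    protein: ProteinRecord,
    domains: Sequence[WrkyDomain],
) -> WrkyAnnotation:
    """Classify a protein by valid-domain count and zinc-finger type."""
    valid = [d for d in domains if d.valid]
    n = len(valid)
    terminal: tuple[str, ...] = ()
    if n == 0:
        group = "unclassified"
    elif n == 1:
        group = "II" if valid[0].zf_type == "C2H2" else "III"
    elif n == 2:
        group = "I"
        terminal = ("N", "C")
    else:
        group = "multi_domain"
    return WrkyAnnotation(
        protein_id=protein.id,
        species=protein.species,
        domains=list(domains),
        n_valid_domains=n,
        group=group,
        terminal_labels=terminal,
    )


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _cosine(a: Counter, b: Counter) -> float:
    dot = sum(v * b[key] for key, v in a.items())
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def assign_subgroup(
    domain_seq: str,
    refs: ReferenceSet,
    k: int = 3,
    floor: float = 0.5,
) -> tuple[str, float, bool]:
    """Label a group II domain by its nearest labeled reference.

    Similarity is cosine similarity of k-mer count vectors over the domain
    span.  Ties are broken alphabetically (and flagged); a best score below
    ``floor`` yields the mixed/unresolved label ``IIm``.
    """
    if not refs.references:
        raise ValueError("reference set is empty")
    query = _kmer_counts(domain_seq.upper(), k)
    best_label, best_score = "", -1.0
    tie = False
    for label in sorted(refs.references):
        score = max(
            _cosine(query, _kmer_counts(ref.upper(), k))
            for ref in refs.references[label]
        )
        if score > best_score + 1e-12:
            best_label, best_score, tie = label, score, False
        elif abs(score - best_score) <= 1e-12:
            tie = True
    if best_score < floor:
        return "IIm", best_score, tie
    return best_label, best_score, tie


def annotate_protein(
    protein: ProteinRecord,
    refs: ReferenceSet | None = None,
    max_mismatch: int = 2,
    window: int = 120,
    k: int = 3,
    floor: float = 0.5,
) -> WrkyAnnotation:
    """Full per-protein pipeline: scan, assemble, classify, subclassify."""
    domains = validate_and_assemble(
        protein, max_mismatch=max_mismatch, window=window
    )
    ann = assign_group(protein, domains)
    if ann.group == "II" and refs is not None:
        dom = next(d for d in domains if d.valid)
        seq = protein.seq[dom.span[0] : dom.span[1]]
        ann.subgroup, ann.subgroup_score, ann.subgroup_tie = assign_subgroup(
            seq, refs, k=k, floor=floor
        )
    return ann


def annotate_proteins(
    proteins: Iterable[ProteinRecord],
    refs: ReferenceSet | None = None,
    **kwargs,
) -> list[WrkyAnnotation]:
    return [annotate_protein(p, refs, **kwargs) for p in proteins]


def table1_report(annotations: Iterable[WrkyAnnotation]) -> pd.DataFrame:
    """Per-species counts of group I / II / III (+ multi-domain) proteins.

    Unclassified proteins (no valid domain) are excluded from the family
    and reported separately by :func:`excluded_report`.
    """
    rows: dict[str, Counter] = {}
    for ann in annotations:
        if ann.group == "unclassified":
            continue
        rows.setdefault(ann.species, Counter())[ann.group] += 1
    if not rows:
        return pd.DataFrame(
            columns=["I", "II", "III", "multi_domain", "total"]
        ).rename_axis("species")
    table = pd.DataFrame(
        [
            {
                "I": c.get("I", 0),
                "II": c.get("II", 0),
                "III": c.get("III", 0),
                "multi_domain": c.get("multi_domain", 0),
            }
            for c in rows.values()
        ],
        index=list(rows),
    ).rename_axis("species")
    table["total"] = table.sum(axis=1)
    return table.sort_index()


def excluded_report(annotations: Iterable[WrkyAnnotation]) -> pd.DataFrame:
    """Proteins excluded from the family (no valid domain), with the reason."""
    rows = []
    for ann in annotations:
        if ann.group != "unclassified":
            continue
        reason = "no heptapeptide seed" if not ann.domains else "no zinc finger"
        rows.append(
            {"protein": ann.protein_id, "species": ann.species, "reason": reason}
        )
    return pd.DataFrame(rows, columns=["protein", "species", "reason"])


def domains_table(annotations: Iterable[WrkyAnnotation], one_based: bool = False) -> pd.DataFrame:
    """Flat per-domain report (offsets half-open, 0-based unless asked)."""
    shift = 1 if one_based else 0
    rows = []
    for ann in annotations:
        for dom in ann.domains:
            rows.append(
                {
                    "protein": dom.protein_id,
                    "species": ann.species,
                    "heptapeptide": dom.heptapeptide,
                    "hepta_start": dom.hepta_start + shift,
                    "mismatches": dom.n_mismatches,
                    "zf_type": dom.zf_type,
                    "zf_x1": dom.zf_spacers[0] if dom.zf_spacers else "",
                    "zf_x2": dom.zf_spacers[1] if dom.zf_spacers else "",
                    # 1-based reports are inclusive, so the end stays put
                    "start": dom.span[0] + shift,
                    "end": dom.span[1],
                    "valid": dom.valid,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["protein", "species", "heptapeptide", "hepta_start",
                 "mismatches", "zf_type", "zf_x1", "zf_x2", "start", "end",
                 "valid"],
    )
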