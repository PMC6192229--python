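"""Ortholog/paralog identification by pairwise similarity thresholds.

A candidate gene pair is accepted as homologous when the aligned region
covers more than 80% of each sequence, identity exceeds 80%, and (when a
precomputed hit table supplies one) the E-value is at most 1e-10.  Pairs
within one species are paralogs, pairs between species are orthologs.
When no hit table is given, an internal global (Needleman-Wunsch, affine
gap) aligner computes coverage and identity and the E-value criterion is
waived — a full-length aligner has no search statistics.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .io_formats import CdsRecord, HitRecord


@dataclass
class HomologPair:
    """A candidate homolog pair with the threshold evidence and pass flag."""

    a: str
    b: str
    species_a: str
    species_b: str
    relation: str            # paralog | ortholog
    coverage_a: float
    coverage_b: float
    identity: float
    evalue: float | None = None
    passed: bool = False


_cds_aligner: Align.PairwiseAligner | None = None


def _get_cds_aligner() -> Align.PairwiseAligner:
    global _cds_aligner
    if _cds_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
        # end gaps are free: length differences show up in coverage, not
        # as gap penalties distorting the internal alignment
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older PairwiseAligner API
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
        _cds_aligner = aligner
    return _cds_aligner


def align_cds_pair(
    a: CdsRecord | str, b: CdsRecord | str
) -> tuple[float, float, float]:
    """Global-align two CDSs; return (coverage_a, coverage_b, identity).

    Identity is matches over aligned columns excluding end gaps (percent);
    each coverage is the fraction of that sequence falling inside the
    identity-counted region.
    """
    seq_a = (a.seq if isinstance(a, CdsRecord) else a).upper()
    seq_b = (b.seq if isinstance(b, CdsRecord) else b).upper()
    aln = _get_cds_aligner().align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # Trim end gaps: region where both sequences have started and not ended.
    first = 0
    last = len(row_a)
    for i in range(len(row_a)):
        if row_a[i] != "-" and row_b[i] != "-":
            first = i
            break
    else:
        return 0.0, 0.0, 0.0
    for i in range(len(row_a) - 1, -1, -1):
        if row_a[i] != "-" and row_b[i] != "-":
            last = i + 1
            break
    ra, rb = row_a[first:last], row_b[first:last]
    columns = len(ra)
    matches = sum(x == y and x != "-" for x, y in zip(ra, rb))
    identity = 100.0 * matches / columns if columns else 0.0
    cov_a = sum(x != "-" for x in ra) / len(seq_a)
    cov_b = sum(x != "-" for x in rb) / len(seq_b)
    return cov_a, cov_b, identity


def _passes(
    cov_a: float, cov_b: float, identity: float, evalue: float | None,
    min_identity: float, min_coverage: float, max_evalue: float,
) -> bool:
    ok = cov_a > min_coverage and cov_b > min_coverage and identity > min_identity
    if evalue is not None:
        ok = ok and evalue <= max_evalue
    return ok


def pair_homologs(
    genes: Sequence[CdsRecord],
    mode: str = "internal",
    hits: Iterable[HitRecord] | None = None,
    min_identity: float = 80.0,
    min_coverage: float = 0.8,
    max_evalue: float = 1e-10,
    rbh: bool = False,
) -> list[HomologPair]:
    """Evaluate all candidate pairs against the homology thresholds.

    ``internal`` mode aligns every unordered gene pair (E-value waived);
    ``hit_table`` mode consumes a precomputed hit list, keeping the single
    best-E-value row per unordered pair.  Every evaluated pair is returned
    with its ``passed`` flag; with ``rbh=True`` passing between-species
    pairs are additionally required to be reciprocal best matches.
    """
    by_id: dict[str, CdsRecord] = {}
    for g in genes:
        if g.id in by_id:
            raise ValueError(f"duplicate gene id {g.id!r}")
        by_id[g.id] = g
    pairs: list[HomologPair] = []
    if mode == "internal":
        for ga, gb in itertools.combinations(genes, 2):
            cov_a, cov_b, ident = align_cds_pair(ga, gb)
            pairs.append(_make_pair(ga, gb, cov_a, cov_b, ident, None,
                                    min_identity, min_coverage, max_evalue))
    elif mode in ("hit_table", "hits"):
        if hits is None:
            raise ValueError("hit_table mode requires a hit list")
        best: dict[tuple[str, str], HitRecord] = {}
        for hit in hits:
            if hit.query == hit.subject:
                continue
            for gid in (hit.query, hit.subject):
                if gid not in by_id:
                    raise ValueError(
                        f"hit references id {gid!r} absent from the CDS set"
                    )
            key = tuple(sorted((hit.query, hit.subject)))
            if key not in best or hit.evalue < best[key].evalue:
                best[key] = hit
        for key in sorted(best):
            hit = best[key]
            ga, gb = by_id[hit.query], by_id[hit.subject]
            cov_a = hit.aln_len / hit.qlen
            cov_b = hit.aln_len / hit.slen
            pairs.append(_make_pair(ga, gb, cov_a, cov_b, hit.identity,
                                    hit.evalue, min_identity, min_coverage,
                                    max_evalue))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if rbh:
        _apply_rbh(pairs)
    return pairs


def _make_pair(ga, gb, cov_a, cov_b, identity, evalue,
               min_identity, min_coverage, max_evalue) -> HomologPair:
    relation = "paralog" if ga.species == gb.species else "ortholog"
    return HomologPair(
        a=ga.id, b=gb.id, species_a=ga.species, species_b=gb.species,
        relation=relation, coverage_a=cov_a, coverage_b=cov_b,
        identity=identity, evalue=evalue,
        passed=_passes(cov_a, cov_b, identity, evalue,
                       min_identity, min_coverage, max_evalue),
    )


def _apply_rbh(pairs: list[HomologPair]) -> None:
    """Demote passing ortholog pairs that are not reciprocal best matches
    (best = highest identity per gene per partner species)."""
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for p in pairs:
        if p.relation != "ortholog" or not p.passed:
            continue
        for gid, sp, other in ((p.a, p.species_b, p.b), (p.b, p.species_a, p.a)):
            key = (gid, sp)
            if key not in best or p.identity > best[key][0]:
                best[key] = (p.identity, other)
    for p in pairs:
        if p.relation != "ortholog" or not p.passed:
            continue
        if best[(p.a, p.species_b)][1] != p.b or best[(p.b, p.species_a)][1] != p.a:
            p.passed = False


def homologs_table(pairs: Iterable[HomologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "a": p.a, "b": p.b, "species_a": p.species_a,
                "species_b": p.species_b, "relation": p.relation,
                "coverage_a": p.coverage_a, "coverage_b": p.coverage_b,
                "identity": p.identity,
                "evalue": p.evalue if p.evalue is not None else "",
                "pass": p.passed,
            }
            for p in pairs
        ],
        columns=["a", "b", "species_a", "species_b", "relation",
                 "coverage_a", "coverage_b", "identity", "evalue", "pass"],
    )
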