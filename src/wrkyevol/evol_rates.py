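"""Codon alignments and Nei-Gojobori (1986) Ka/Ks estimation.

The counting estimator works on a pairwise codon alignment obtained by
back-translating an amino-acid alignment onto the source CDSs.  Per codon,
each position contributes ``(synonymous one-step changes)/3`` synonymous
sites (averaged over the two sequences); codon pairs differing at several
positions are scored by averaging the synonymous/nonsynonymous step counts
over all minimal mutational pathways with equal weights, discarding
pathways that pass through a stop codon.  The raw proportions pN = Nd/N and
pS = Sd/S are corrected for multiple hits with the Jukes-Cantor formula
``d = -(3/4) ln(1 - 4p/3)``.

Ka/Ks < 1 indicates purifying selection, = 1 neutral evolution and > 1
positive selection.  Pairs with Ks below 0.01 (unstable estimates at low
divergence) or above 3 (saturation) are filtered from downstream summaries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product
from typing import Iterable

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy import stats

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"
CODONS = tuple("".join(c) for c in product("TCAG", repeat=3))
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)

NEUTRAL_TOL = 1e-9  # |Ka/Ks - 1| below this counts as neutral


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Changes to stop codons count as nonsynonymous, so the two always sum
    to exactly 3.
    """
    if codon not in GENETIC_CODE or codon in STOP_CODONS:
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal pathways.

    Pathways passing through a stop codon are discarded; in the (rare)
    event that every pathway is blocked, all pathways are used so the pair
    still contributes its differences.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in GENETIC_CODE:
            raise ValueError(f"not a sense codon: {c!r}")
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stop: bool) -> tuple[int, int] | None:
        cur, sd, nd = codon_a, 0, 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if not allow_stop and nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    orders = list(permutations(diffs))
    paths = [w for o in orders if (w := walk(o, allow_stop=False)) is not None]
    if not paths:
        paths = [walk(o, allow_stop=True) for o in orders]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN at/beyond the p = 3/4 ceiling."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class CodonAlignment:
    """Paired codon columns for two genes; ``---`` marks an alignment gap."""

    id_a: str
    id_b: str
    columns: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class RateEstimate:
    """NG86 estimate for one gene pair."""

    id_a: str
    id_b: str
    ka: float
    ks: float
    ratio: float            # NaN when undefined (Ks = 0 or saturated)
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    codons_compared: int
    codons_skipped: int
    filter: str             # retained | excluded_low | excluded_high | undefined
    selection: str          # purifying | neutral | positive | NA


def _trim_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def translate_cds(cds: str) -> str:
    """Standard-code translation; codons containing N translate to X."""
    cds = _trim_stop(cds.upper())
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(GENETIC_CODE[codon])
    return "".join(out)


def back_translate(
    aln_a: str,
    aln_b: str,
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Thread source codons onto an aligned amino-acid pair.

    Each amino-acid column becomes its source codon (or ``---`` at a gap);
    any mismatch between a CDS translation and its aligned protein is a
    hard error naming the gene and 1-based position.
    """
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned sequences differ in length")
    cols: list[tuple[str, str]] = []
    cursors = [0, 0]
    seqs = [_trim_stop(cds_a.upper()), _trim_stop(cds_b.upper())]
    ids = (id_a, id_b)
    for name, aln, cds in zip(ids, (aln_a, aln_b), seqs):
        n_aa = sum(1 for ch in aln if ch != "-")
        if len(cds) != 3 * n_aa:
            raise ValueError(
                f"{name}: CDS length {len(cds)} does not match "
                f"{n_aa} aligned residues (expected {3 * n_aa})"
            )
    for col, (ra, rb) in enumerate(zip(aln_a, aln_b)):
        pair = []
        for k, (name, res) in enumerate(zip(ids, (ra, rb))):
            if res == "-":
                pair.append("---")
                continue
            codon = seqs[k][cursors[k] : cursors[k] + 3]
            cursors[k] += 3
            aa = "X" if "N" in codon else GENETIC_CODE[codon]
            if aa == "*":
                raise ValueError(
                    f"{name}: internal stop codon at residue "
                    f"{cursors[k] // 3}"
                )
            if res.upper() not in (aa, "X") and aa != "X":
                raise ValueError(
                    f"{name}: translation mismatch at position "
                    f"{cursors[k] // 3}: codon {codon} -> {aa}, "
                    f"alignment has {res}"
                )
            pair.append(codon)
        cols.append((pair[0], pair[1]))
    return CodonAlignment(id_a=id_a, id_b=id_b, columns=tuple(cols))


def nei_gojobori(aln: CodonAlignment) -> RateEstimate:
    """NG86 Ka/Ks for one codon alignment.

    Columns containing a gap, an N or a stop codon are skipped (and
    counted).  The ratio is undefined when Ks = 0 or when pS reaches the
    Jukes-Cantor ceiling (3/4); such pairs carry ``filter='undefined'``.
    """
    syn_a = syn_b = 0.0
    sd_total = nd_total = 0.0
    compared = skipped = 0
    for ca, cb in aln.columns:
        if ca not in GENETIC_CODE or cb not in GENETIC_CODE \
                or ca in STOP_CODONS or cb in STOP_CODONS:
            skipped += 1
            continue
        sa, _ = codon_sites(ca)
        sb, _ = codon_sites(cb)
        syn_a += sa
        syn_b += sb
        sd, nd = codon_pair_differences(ca, cb)
        sd_total += sd
        nd_total += nd
        compared += 1
    if compared == 0:
        raise ValueError(
            f"{aln.id_a}/{aln.id_b}: no comparable codon columns"
        )
    s_sites = (syn_a + syn_b) / 2.0
    n_sites = 3.0 * compared - s_sites
    p_s = sd_total / s_sites if s_sites > 0 else float("nan")
    p_n = nd_total / n_sites if n_sites > 0 else float("nan")
    ks = jukes_cantor(p_s) if not math.isnan(p_s) else float("nan")
    ka = jukes_cantor(p_n) if not math.isnan(p_n) else float("nan")
    undefined = (
        math.isnan(ks) or math.isnan(ka) or ks == 0.0
    )
    if undefined:
        ratio = float("nan")
        filt, sel = "undefined", "NA"
    else:
        ratio = ka / ks
        filt = "retained"
        if abs(ratio - 1.0) <= NEUTRAL_TOL:
            sel = "neutral"
        elif ratio < 1.0:
            sel = "purifying"
        else:
            sel = "positive"
    return RateEstimate(
        id_a=aln.id_a, id_b=aln.id_b, ka=ka, ks=ks, ratio=ratio,
        n_sites=n_sites, s_sites=s_sites, nd=nd_total, sd=sd_total,
        codons_compared=compared, codons_skipped=skipped,
        filter=filt, selection=sel,
    )


_protein_aligner: Align.PairwiseAligner | None = None


def _get_protein_aligner() -> Align.PairwiseAligner:
    global _protein_aligner
    if _protein_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _protein_aligner = aligner
    return _protein_aligner


def align_protein_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, affine gaps)."""
    aln = _get_protein_aligner().align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def kaks_for_cds_pair(
    cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b"
) -> RateEstimate:
    """Protein-guided codon alignment + NG86 for one CDS pair."""
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aln_a, aln_b = align_protein_pair(prot_a, prot_b)
    codon_aln = back_translate(aln_a, aln_b, cds_a, cds_b, id_a, id_b)
    return nei_gojobori(codon_aln)


def apply_rate_filters(
    estimates: Iterable[RateEstimate],
    ks_low: float = 0.01,
    ks_high: float = 3.0,
    ka_zero: float = 1e-6,
) -> tuple[list[RateEstimate], pd.DataFrame]:
    """Flag unreliable estimates: Ks < 0.01 (low divergence) or Ks > 3
    (saturation).  Returns the retained estimates and an exclusion report;
    the report notes pairs whose Ka is essentially zero alongside an
    out-of-range Ks.
    """
    retained: list[RateEstimate] = []
    rows = []
    for est in estimates:
        if est.filter == "undefined" or math.isnan(est.ks):
            status, note = "undefined", "ratio undefined"
        elif est.ks < ks_low:
            status = "excluded_low"
            note = "Ka nearly 0" if est.ka < ka_zero else ""
        elif est.ks > ks_high:
            status = "excluded_high"
            note = "Ka nearly 0" if est.ka < ka_zero else ""
        else:
            status, note = "retained", ""
        est.filter = status
        if status == "retained":
            retained.append(est)
        else:
            rows.append(
                {"a": est.id_a, "b": est.id_b, "ka": est.ka, "ks": est.ks,
                 "status": status, "note": note}
            )
    report = pd.DataFrame(rows, columns=["a", "b", "ka", "ks", "status", "note"])
    return retained, report


def rates_table(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "a": e.id_a, "b": e.id_b, "ka": e.ka, "ks": e.ks,
                "ratio": e.ratio, "n_sites": e.n_sites, "s_sites": e.s_sites,
                "nd": e.nd, "sd": e.sd, "codons": e.codons_compared,
                "skipped": e.codons_skipped, "filter": e.filter,
                "selection": e.selection,
            }
            for e in estimates
        ]
    )


def summarize_rates(
    table: pd.DataFrame, by: str = "relation"
) -> pd.DataFrame:
    """Per-class mean Ka/Ks/ratio plus two-sided Mann-Whitney comparisons.

    ``table`` must carry ``ka``, ``ks``, ``ratio`` and the grouping column
    (typically ``relation`` = ortholog/paralog).  With fewer than two
    observations in either class the p-value is NA.
    """
    metrics = ["ka", "ks", "ratio"]
    rows = []
    groups = list(table.groupby(by))
    for name, sub in groups:
        row = {by: name, "n": len(sub)}
        for m in metrics:
            row[f"mean_{m}"] = sub[m].mean()
        rows.append(row)
    summary = pd.DataFrame(rows)
    if len(groups) == 2:
        (_, g1), (_, g2) = groups
        for m in metrics:
            x, y = g1[m].dropna(), g2[m].dropna()
            if len(x) >= 2 and len(y) >= 2:
                _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            else:
                p = float("nan")
            summary[f"p_{m}"] = p
    return summary
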