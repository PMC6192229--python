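"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (Biopython
translation, explicit loops, recursive pathway enumeration) and shares no
code with the package's estimators.
"""
from fractions import Fraction

from Bio.Seq import Seq

BASES = "ACGT"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate_codon(codon) == "*"


def syn_nonsyn_sites(codon: str) -> tuple[Fraction, Fraction]:
    """Exact synonymous/nonsynonymous site counts of one sense codon."""
    aa = translate_codon(codon)
    syn = Fraction(0)
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if translate_codon(mutant) == aa:
                syn += Fraction(1, 3)
    return syn, 3 - syn


def pathway_differences(c1: str, c2: str) -> tuple[Fraction, Fraction]:
    """(Sd, Nd) averaged over all minimal pathways, enumerated recursively;
    pathways through stop codons are discarded, with an all-pathways
    fallback if every route is blocked."""

    def expand(cur: str, allow_stop: bool) -> list[tuple[int, int]]:
        diffs = [i for i in range(3) if cur[i] != c2[i]]
        if not diffs:
            return [(0, 0)]
        results = []
        for pos in diffs:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if not allow_stop and is_stop(nxt) and nxt != c2:
                continue
            step_syn = translate_codon(nxt) == translate_codon(cur)
            for sd, nd in expand(nxt, allow_stop):
                results.append((sd + step_syn, nd + (not step_syn)))
        return results

    paths = expand(c1, allow_stop=False)
    if not paths:
        paths = expand(c1, allow_stop=True)
    n = len(paths)
    sd = sum(Fraction(p[0]) for p in paths) / n
    nd = sum(Fraction(p[1]) for p in paths) / n
    return sd, nd


def gc_by_position_loop(cds: str) -> tuple[float, float, float]:
    """Per-base loop GC1/2/3 oracle (percent), N bases dropped both sides."""
    out = []
    for k in range(3):
        bases = [cds[i] for i in range(k, len(cds), 3) if cds[i] != "N"]
        out.append(100.0 * sum(b in "GC" for b in bases) / len(bases)
                   if bases else float("nan"))
    return tuple(out)


def fop_loop(cds: str, optimal_codons: set[str]) -> float:
    """Per-codon loop Fop oracle (codonW denominator convention)."""
    num = den = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            continue
        aa = translate_codon(codon)
        if aa in "*MW":
            continue
        den += 1
        if codon in optimal_codons:
            num += 1
    return num / den if den else float("nan")


def heptapeptide_windows(seq: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All candidate (offset, mismatch) windows by brute-force scan."""
    hits = []
    for off in range(len(seq) - 6):
        window = seq[off : off + 7]
        if window[0] != "W":
            continue
        mism = sum(a != b for a, b in zip(window, "WRKYGQK"))
        if mism <= max_mismatch:
            hits.append((off, mism))
    return hits
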