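"""Per-gene codon-usage and length features: Fop, GC1/GC2/GC3, length.

Fop (frequency of optimal codons) is the fraction of codons drawn from a
designated optimal set among codons belonging to synonymous families —
Met (ATG), Trp (TGG) and stop codons are excluded from the denominator.
The paper's source program (codonW) does not disclose which optimal set it
applied per organism, so a documented plant-generic set is bundled and the
set id is recorded in every output; callers can supply their own.

GCk is the percent G+C at codon position k; N bases are excluded from both
numerator and denominator position-wise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evol_rates import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, _trim_stop
from .io_formats import CdsRecord

SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_CODONS.setdefault(GENETIC_CODE[_codon], tuple())
SYNONYMOUS_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if GENETIC_CODE[c] == aa)
    for aa in SYNONYMOUS_CODONS
}


@dataclass(frozen=True)
class OptimalCodonSet:
    """Amino acid -> optimal codon(s); Met, Trp and stops are not allowed."""

    set_id: str
    mapping: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for aa, codons in self.mapping.items():
            if aa in ("M", "W", "*"):
                raise ValueError(f"{aa!r} has no synonymous choice")
            for codon in codons:
                if codon in STOP_CODONS or GENETIC_CODE.get(codon) != aa:
                    raise ValueError(f"codon {codon} does not encode {aa}")

    @property
    def codons(self) -> frozenset[str]:
        return frozenset(c for cs in self.mapping.values() for c in cs)


# A plant-biased default (one preferred codon per synonymous family), in the
# spirit of dicot codon-usage surveys.  Pragmatic default, not organism-tuned;
# replace it for serious per-species work.
DEFAULT_OPTIMAL_CODONS = OptimalCodonSet(
    set_id="plant-generic-v1",
    mapping={
        "F": ("TTC",), "L": ("CTT",), "I": ("ATC",), "V": ("GTT",),
        "S": ("TCT",), "P": ("CCA",), "T": ("ACT",), "A": ("GCT",),
        "Y": ("TAC",), "H": ("CAC",), "Q": ("CAA",), "N": ("AAC",),
        "K": ("AAG",), "D": ("GAT",), "E": ("GAA",), "C": ("TGC",),
        "R": ("AGA",), "G": ("GGA",),
    },
)


@dataclass
class GeneFeatures:
    gene_id: str
    fop: float
    length_aa: int
    gc1: float
    gc2: float
    gc3: float
    counted_codons: int
    optimal_set_id: str


def gc_by_position(cds: str | CdsRecord) -> tuple[float, float, float]:
    """Percent G+C at each codon position; NaN when a position has no
    counted (non-N) bases."""
    seq = (cds.seq if isinstance(cds, CdsRecord) else cds).upper()
    seq = _trim_stop(seq)
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    gc = [0, 0, 0]
    counted = [0, 0, 0]
    for i, base in enumerate(seq):
        pos = i % 3
        if base == "N":
            continue
        counted[pos] += 1
        if base in "GC":
            gc[pos] += 1
    return tuple(
        100.0 * gc[k] / counted[k] if counted[k] else float("nan")
        for k in range(3)
    )


def fop(cds: str | CdsRecord, optimal: OptimalCodonSet = DEFAULT_OPTIMAL_CODONS) -> float:
    """Frequency of optimal codons.

    Denominator: codons whose amino acid has a synonymous choice (Met, Trp,
    stops and N-containing codons excluded).  NaN on an empty denominator.
    """
    seq = (cds.seq if isinstance(cds, CdsRecord) else cds).upper()
    seq = _trim_stop(seq)
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    optimal_codons = optimal.codons
    num = den = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon or codon in STOP_CODONS:
            continue
        aa = GENETIC_CODE[codon]
        if len(SYNONYMOUS_CODONS[aa]) < 2:
            continue  # Met, Trp
        den += 1
        if codon in optimal_codons:
            num += 1
    return num / den if den else float("nan")


def compute_features(
    genes: Iterable[CdsRecord],
    optimal: OptimalCodonSet = DEFAULT_OPTIMAL_CODONS,
) -> pd.DataFrame:
    """Per-gene feature table indexed by gene id."""
    rows = []
    for gene in genes:
        seq = _trim_stop(gene.seq.upper())
        gc1, gc2, gc3 = gc_by_position(seq)
        rows.append(
            {
                "gene": gene.id, "species": gene.species,
                "fop": fop(seq, optimal), "length_aa": len(seq) // 3,
                "gc1": gc1, "gc2": gc2, "gc3": gc3,
                "counted_codons": len(seq) // 3,
                "optimal_set_id": optimal.set_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "species", "fop", "length_aa", "gc1", "gc2", "gc3",
                 "counted_codons", "optimal_set_id"],
    ).set_index("gene")


FEATURE_COLUMNS = ("fop", "length_aa", "gc1", "gc2", "gc3")


def feature_table(
    genes: Sequence[CdsRecord],
    duplicated_ids: Iterable[str],
    optimal: OptimalCodonSet = DEFAULT_OPTIMAL_CODONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Duplicate-vs-singleton feature comparison.

    ``duplicated_ids`` are genes belonging to at least one passing paralog
    pair; every other gene counts as a singleton.  Returns the per-gene
    table and a per-feature comparison (mean +/- SD per class, two-sided
    Mann-Whitney p; NA with fewer than two genes in a class).
    """
    from scipy import stats

    feats = compute_features(genes, optimal)
    dup = set(duplicated_ids)
    feats["class"] = [
        "duplicate" if g in dup else "singleton" for g in feats.index
    ]
    rows = []
    for col in FEATURE_COLUMNS:
        x = feats.loc[feats["class"] == "duplicate", col].dropna()
        y = feats.loc[feats["class"] == "singleton", col].dropna()
        if len(x) >= 2 and len(y) >= 2:
            _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        else:
            p = float("nan")
        rows.append(
            {
                "feature": col,
                "duplicate_mean": x.mean() if len(x) else float("nan"),
                "duplicate_sd": x.std(ddof=1) if len(x) > 1 else float("nan"),
                "singleton_mean": y.mean() if len(y) else float("nan"),
                "singleton_sd": y.std(ddof=1) if len(y) > 1 else float("nan"),
                "n_duplicate": len(x), "n_singleton": len(y), "p": p,
            }
        )
    comparison = pd.DataFrame(rows).set_index("feature")
    return feats, comparison
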