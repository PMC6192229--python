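"""Fully labeled synthetic cohorts with the structure the pipeline assumes.

The generator emulates a multi-species WRKY gene-family dataset: proteins
of groups I / IIa-IIe / III built from an explicit pattern grammar
(heptapeptide + class-correct zinc finger), planted heptapeptide variants,
non-WRKY decoys, duplicate and cross-species gene copies evolved under a
selectable dN/dS with a target synonymous divergence, codon usage with a
per-gene optimal-codon propensity, and tissue expression profiles with
planted fold-divergence.  Everything carries machine-readable ground truth
so every downstream stage has an exact oracle.

Flanks, linkers and zinc-finger spacer filler never contain W, C or H, and
evolution of copies never introduces those letters outside planted motifs
nor touches planted domain spans nonsynonymously, so planted labels remain
exactly recoverable.  Identical configurations (including the seed)
reproduce byte-identical cohorts.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .domain_model import CANONICAL_HEPTAPEPTIDE, ReferenceSet
from .evol_rates import (
    GENETIC_CODE, STOP_CODONS, codon_pair_differences, codon_sites,
    jukes_cantor,
)
from .gene_features import DEFAULT_OPTIMAL_CODONS, SYNONYMOUS_CODONS, OptimalCodonSet
from .io_formats import CdsRecord, ProteinRecord, write_expression, write_fasta

#: Flank/linker/spacer alphabet: no W (seed anchor), no C/H (zinc-finger
#: letters), so planted motifs are the only motifs.
SAFE_AA = "ADEFGIKLMNPQRSTVY"

TISSUE_NAMES = (
    "young_leaves", "flowers", "one_cm_pods", "pod_shell_10DAF",
    "pod_shell_14DAF", "seeds_10DAF", "seeds_14DAF", "seeds_21DAF",
    "seeds_25DAF", "seeds_28DAF", "seeds_35DAF", "seeds_42DAF",
    "roots", "nodules",
)

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _span(offset: int, n: int) -> str:
    """Deterministic filler string over SAFE_AA (distinct per offset)."""
    m = len(SAFE_AA)
    return "".join(SAFE_AA[(offset + 5 * i) % m] for i in range(n))


def _c2h2(x1: int, x2: int, off: int) -> str:
    return "C" + _span(off, x1) + "C" + _span(off + 3, x2) + "H" + _span(off + 7, 1) + "H"


def _c2hc(off: int) -> str:
    return "C" + _span(off, 7) + "C" + _span(off + 3, 23) + "H" + _span(off + 7, 1) + "C"


#: Template domain per architectural slot; group II subgroups get distinct
#: linkers/spacer filler so nearest-reference assignment is unambiguous.
DOMAIN_TEMPLATES: dict[str, str] = {
    "I_N": CANONICAL_HEPTAPEPTIDE + _span(1, 8) + _c2h2(4, 22, 2),
    "I_C": CANONICAL_HEPTAPEPTIDE + _span(21, 8) + _c2h2(5, 23, 9),
    "IIa": CANONICAL_HEPTAPEPTIDE + _span(31, 8) + _c2h2(4, 22, 11),
    "IIb": CANONICAL_HEPTAPEPTIDE + _span(41, 8) + _c2h2(4, 23, 13),
    "IIc": CANONICAL_HEPTAPEPTIDE + _span(51, 8) + _c2h2(5, 22, 3),
    "IId": CANONICAL_HEPTAPEPTIDE + _span(61, 8) + _c2h2(5, 23, 5),
    "IIe": CANONICAL_HEPTAPEPTIDE + _span(71, 8) + _c2h2(4, 22, 7),
    "III": CANONICAL_HEPTAPEPTIDE + _span(81, 8) + _c2hc(4),
}

_GROUP_DOMAINS: dict[str, tuple[str, ...]] = {
    "I": ("I_N", "I_C"),
    "IIa": ("IIa",), "IIb": ("IIb",), "IIc": ("IIc",),
    "IId": ("IId",), "IIe": ("IIe",),
    "III": ("III",),
    "multi": ("I_N", "I_C", "I_N"),
}


def reference_set() -> ReferenceSet:
    """The generating subgroup templates as a labeled reference set."""
    return ReferenceSet(
        {label: [DOMAIN_TEMPLATES[label]] for label in
         ("IIa", "IIb", "IIc", "IId", "IIe")}
    )


def _random_safe(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(SAFE_AA), size=n)
    return "".join(SAFE_AA[i] for i in idx)


def gen_wrky_protein(
    group: str,
    subgroup: str | None = None,
    variant: Mapping[int, str] | None = None,
    rng: np.random.Generator | None = None,
    flank_len: tuple[int, int] = (25, 60),
    linker_len: tuple[int, int] = (20, 35),
) -> tuple[str, dict]:
    """Build one labeled WRKY protein from the pattern grammar.

    ``group`` is one of I, IIa..IIe, III, multi (``subgroup`` may name the
    group II template instead).  ``variant`` maps heptapeptide positions
    2..7 to replacement residues, applied to the first domain.  Returns the
    sequence and a truth dict with domain spans.
    """
    rng = rng if rng is not None else np.random.default_rng()
    key = subgroup or group
    if key not in _GROUP_DOMAINS:
        raise ValueError(f"unknown group/subgroup {key!r}")
    templates = [DOMAIN_TEMPLATES[name] for name in _GROUP_DOMAINS[key]]
    if variant:
        dom = list(templates[0])
        for pos, aa in variant.items():
            if not 2 <= pos <= 7:
                raise ValueError("variant positions must be in 2..7 (W anchored)")
            dom[pos - 1] = aa
        templates[0] = "".join(dom)
    parts: list[str] = [_random_safe(rng, int(rng.integers(*flank_len)))]
    spans: list[tuple[int, int]] = []
    heptas: list[str] = []
    for j, dom in enumerate(templates):
        if j:
            parts.append(_random_safe(rng, int(rng.integers(*linker_len))))
        start = sum(len(p) for p in parts)
        parts.append(dom)
        spans.append((start, start + len(dom)))
        heptas.append(dom[:7])
    parts.append(_random_safe(rng, int(rng.integers(*flank_len))))
    seq = "".join(parts)
    truth = {
        "group": "I" if key == "I" else ("multi_domain" if key == "multi"
                 else ("III" if key == "III" else "II")),
        "subgroup": key if key.startswith("II") else "none",
        "domain_spans": spans,
        "heptapeptides": heptas,
    }
    return seq, truth


def gen_decoy_protein(
    kind: str,
    rng: np.random.Generator,
    length: tuple[int, int] = (80, 200),
) -> str:
    """A non-WRKY decoy: ``no_hepta`` lacks any W (so no seed can exist);
    ``no_zf`` carries a canonical heptapeptide but no cysteine downstream.
    """
    n = int(rng.integers(*length))
    if kind == "no_hepta":
        # C/H allowed: a zinc finger without a heptapeptide is still a decoy
        alphabet = SAFE_AA + "CH"
        idx = rng.integers(0, len(alphabet), size=n)
        return "".join(alphabet[i] for i in idx)
    if kind == "no_zf":
        half = n // 2
        return (_random_safe(rng, half) + CANONICAL_HEPTAPEPTIDE
                + _random_safe(rng, n - half))
    raise ValueError(f"unknown decoy kind {kind!r}")


def reverse_translate(
    protein: str,
    rng: np.random.Generator,
    p_opt: float = 0.5,
    optimal: OptimalCodonSet = DEFAULT_OPTIMAL_CODONS,
) -> str:
    """Sample an in-frame CDS encoding ``protein``.

    Each codon with a synonymous choice is the family's optimal codon with
    probability ``p_opt``, else uniform over the non-optimal synonyms — so
    a gene's expected Fop is approximately ``p_opt``.
    """
    codons: list[str] = []
    for aa in protein:
        syn = SYNONYMOUS_CODONS[aa]
        opt = optimal.mapping.get(aa)
        if opt and len(syn) > 1:
            if rng.random() < p_opt:
                codons.append(opt[int(rng.integers(len(opt)))])
            else:
                rest = [c for c in syn if c not in opt]
                codons.append(rest[int(rng.integers(len(rest)))])
        else:
            codons.append(syn[int(rng.integers(len(syn)))])
    return "".join(codons)


def _evolve(
    cds: str,
    omega: float,
    target_ks: float,
    rng: np.random.Generator,
    n_lineages: int = 2,
    protected_codons: frozenset[int] | set[int] = frozenset(),
    forbidden_new_aa: frozenset[str] | set[str] = frozenset(),
    kappa: float = 1.0,
    max_proposals: int | None = None,
) -> tuple[list[str], dict]:
    """Accept/reject codon point-mutation process up to a target Ks.

    Proposals are uniform over positions and (for kappa = 1) alternative
    bases; synonymous changes are always accepted, nonsynonymous ones with
    probability ``omega``; proposals creating stop codons are rejected.
    Divergence is tracked by the same pathway-counting rules as the
    estimator, Jukes-Cantor corrected, and the process stops once it
    reaches ``target_ks``.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons0 = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for c in codons0:
        if c in STOP_CODONS or c not in GENETIC_CODE:
            raise ValueError(f"ancestral CDS contains non-sense codon {c}")
    ncod = len(codons0)
    seqs = [list(codons0) for _ in range(n_lineages)]

    def column(i: int) -> tuple[str, str]:
        ca = seqs[0][i]
        cb = seqs[1][i] if n_lineages == 2 else codons0[i]
        return ca, cb

    syn_sites = [0.0] * ncod
    sd = [0.0] * ncod
    nd = [0.0] * ncod
    for i in range(ncod):
        ca, cb = column(i)
        syn_sites[i] = (codon_sites(ca)[0] + codon_sites(cb)[0]) / 2.0
    s_sum = sum(syn_sites)
    sd_sum = nd_sum = 0.0

    syn_subs = nonsyn_subs = 0
    proposals = 0
    cap = max_proposals if max_proposals is not None else 2000 * ncod
    while proposals < cap:
        proposals += 1
        k = int(rng.integers(n_lineages))
        i = int(rng.integers(ncod))
        p = int(rng.integers(3))
        old = seqs[k][i]
        ob = old[p]
        alts = [b for b in "ACGT" if b != ob]
        if kappa == 1.0:
            nb = alts[int(rng.integers(3))]
        else:
            weights = [kappa if b == _TRANSITIONS[ob] else 1.0 for b in alts]
            u = rng.random() * sum(weights)
            acc = 0.0
            nb = alts[-1]
            for b, w in zip(alts, weights):
                acc += w
                if u < acc:
                    nb = b
                    break
        new = old[:p] + nb + old[p + 1 :]
        if new in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[new] == GENETIC_CODE[old]
        if not synonymous:
            if i in protected_codons:
                continue
            if GENETIC_CODE[new] in forbidden_new_aa:
                continue
            if rng.random() >= omega:
                continue
        seqs[k][i] = new
        if synonymous:
            syn_subs += 1
        else:
            nonsyn_subs += 1
        ca, cb = column(i)
        s_sum -= syn_sites[i]
        sd_sum -= sd[i]
        nd_sum -= nd[i]
        syn_sites[i] = (codon_sites(ca)[0] + codon_sites(cb)[0]) / 2.0
        sd[i], nd[i] = codon_pair_differences(ca, cb)
        s_sum += syn_sites[i]
        sd_sum += sd[i]
        nd_sum += nd[i]
        p_s = sd_sum / s_sum
        if p_s < 0.75 and jukes_cantor(p_s) >= target_ks:
            break
    n_sum = 3.0 * ncod - s_sum
    p_s = sd_sum / s_sum
    p_n = nd_sum / n_sum
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    truth = {
        "omega": omega,
        "target_ks": target_ks,
        "realized_ks": ks,
        "realized_ka": ka,
        "realized_ratio": ka / ks if ks and not math.isnan(ks) else float("nan"),
        "syn_subs": syn_subs,
        "nonsyn_subs": nonsyn_subs,
        "proposals": proposals,
    }
    return ["".join(s) for s in seqs], truth


def evolve_pair(
    cds: str,
    omega: float,
    target_ks: float,
    rng: np.random.Generator,
    **kwargs,
) -> tuple[str, str, dict]:
    """Evolve two descendants of an ancestral CDS to a target pairwise Ks."""
    (a, b), truth = _evolve(cds, omega, target_ks, rng, n_lineages=2, **kwargs)
    return a, b, truth


@dataclass
class SimConfig:
    """Study conditions of a synthetic cohort (all rates/sizes planted)."""

    seed: int = 0
    n_species: int = 3
    genes_per_species: int = 60
    composition: dict[str, float] = field(default_factory=lambda: {
        "I": 0.14, "IIa": 0.12, "IIb": 0.12, "IIc": 0.12, "IId": 0.12,
        "IIe": 0.12, "III": 0.14, "multi": 0.02, "decoy": 0.10,
    })
    variant_rate: float = 0.13
    variant_position_weights: dict[int, float] = field(default_factory=lambda: {
        2: 0.08, 3: 0.08, 4: 0.08, 5: 0.12, 6: 0.50, 7: 0.14,
    })
    variant_q_to_k: float = 0.7
    duplicate_fraction: float = 0.30
    ortholog_fraction: float = 0.25
    paralog_omega: float = 0.34
    paralog_ks: float = 0.19
    ortholog_omega: float = 0.28
    ortholog_ks: float = 0.34
    ks_jitter_sd: float = 0.30
    fop_coupling: float = 1.5
    expr_coupling: float = 0.8
    p_opt_range: tuple[float, float] = (0.2, 0.8)
    n_tissues: int = 14
    expr_log_mu: float = 3.0
    expr_log_sigma: float = 1.5
    expr_tissue_sigma: float = 0.5
    divergence_fraction: float = 0.5
    divergence_effect: tuple[float, float] = (1.5, 3.0)
    expr_noise_sd: float = 0.15
    flank_len: tuple[int, int] = (25, 60)
    kappa: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        if self.paralog_omega <= 0 or self.ortholog_omega <= 0:
            raise ValueError("planted dN/dS must be positive")
        if self.n_tissues < 1:
            raise ValueError("need at least one tissue")


@dataclass
class CohortBundle:
    proteins: list[ProteinRecord]
    cds: list[CdsRecord]
    expression: pd.DataFrame
    labels: pd.DataFrame
    pairs: pd.DataFrame
    references: ReferenceSet
    tissues: tuple[str, ...]
    config: SimConfig


@dataclass
class _Gene:
    id: str
    species: str
    family: str
    category: str           # I | IIa..IIe | III | multi | decoy
    group: str              # expected classifier group
    subgroup: str
    variant: str
    p_opt: float
    protein: str
    cds: str
    domain_spans: list[tuple[int, int]]
    baseline: np.ndarray    # RPKM per tissue
    is_decoy: bool


def _allocate(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation so planted composition is exact."""
    raw = {k: fractions[k] * n for k in fractions}
    base = {k: int(math.floor(v)) for k, v in raw.items()}
    leftover = n - sum(base.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:leftover]:
        base[k] += 1
    return base


def _sample_variant(cfg: SimConfig, rng: np.random.Generator) -> tuple[dict[int, str] | None, str]:
    if rng.random() >= cfg.variant_rate:
        return None, ""
    positions = sorted(cfg.variant_position_weights)
    weights = np.array([cfg.variant_position_weights[p] for p in positions], dtype=float)
    weights /= weights.sum()
    pos = int(rng.choice(positions, p=weights))
    ref = CANONICAL_HEPTAPEPTIDE[pos - 1]
    if pos == 6 and rng.random() < cfg.variant_q_to_k:
        aa = "K"
    else:
        choices = [a for a in SAFE_AA if a != ref]
        aa = choices[int(rng.integers(len(choices)))]
    if aa == ref:  # SAFE_AA may not contain ref, but guard anyway
        aa = "K" if ref != "K" else "R"
    return {pos: aa}, f"{pos}:{ref}>{aa}"


def _coupled_omega(cfg: SimConfig, base: float, p_opt: float, baseline: np.ndarray) -> float:
    mu2 = cfg.expr_log_mu / math.log(2)
    sigma_gene = math.sqrt(max(cfg.expr_log_sigma**2 - cfg.expr_tissue_sigma**2,
                               1e-12))
    z = (float(np.mean(np.log2(baseline))) - mu2) / (sigma_gene / math.log(2))
    omega = base * math.exp(-cfg.fop_coupling * (p_opt - 0.5) * 2.0)
    omega *= math.exp(-cfg.expr_coupling * z)
    # the accept/reject evolver cannot realize omega > 1, so cap there
    return float(np.clip(omega, 0.02, 1.0))


def _jittered_ks(cfg: SimConfig, base: float, rng: np.random.Generator) -> float:
    return float(np.clip(base * math.exp(rng.normal(0.0, cfg.ks_jitter_sd)), 0.02, 2.5))


def _protected_codons(spans: Iterable[tuple[int, int]]) -> frozenset[int]:
    out: set[int] = set()
    for start, end in spans:
        out.update(range(start, end))
    return frozenset(out)


def gen_cohort(config: SimConfig) -> CohortBundle:
    """Generate a complete labeled cohort under the configured conditions.

    Species 1 genes are drawn fresh from the pattern grammar; later species
    receive a planted fraction of cross-species copies (orthologs) evolved
    from species-1 donors, and every species receives within-species copies
    (paralogs) of a planted fraction of its genes.  Copy evolution is
    one-sided so previously recorded truth stays valid.  Expression
    divergence is planted on an exact count of the paralog pairs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tissues = tuple(TISSUE_NAMES[: cfg.n_tissues]) if cfg.n_tissues <= len(TISSUE_NAMES) \
        else tuple(TISSUE_NAMES) + tuple(
            f"tissue_{i}" for i in range(len(TISSUE_NAMES) + 1, cfg.n_tissues + 1))
    genes: list[_Gene] = []
    pair_rows: list[dict] = []
    counter = {"n": 0}

    def next_id(species: str) -> str:
        counter["n"] += 1
        return f"{species}_g{counter['n']:04d}"

    def make_fresh(species: str, category: str, decoy_kind: str) -> _Gene:
        gid = next_id(species)
        p_opt = float(rng.uniform(*cfg.p_opt_range))
        # gene-level abundance shared across tissues + per-tissue variation;
        # the marginal stays lognormal(mu, sigma) on the RPKM scale
        sigma_gene = math.sqrt(max(cfg.expr_log_sigma**2
                                   - cfg.expr_tissue_sigma**2, 0.0))
        gene_level = rng.normal(0.0, sigma_gene)
        tissue_dev = rng.normal(0.0, cfg.expr_tissue_sigma, size=len(tissues))
        baseline = np.exp(cfg.expr_log_mu + gene_level + tissue_dev)
        if category == "decoy":
            protein = gen_decoy_protein(decoy_kind, rng)
            spans: list[tuple[int, int]] = []
            group, subgroup, vstr = "unclassified", "none", ""
        else:
            variant, vstr = _sample_variant(cfg, rng)
            protein, truth = gen_wrky_protein(
                category, variant=variant, rng=rng, flank_len=cfg.flank_len
            )
            spans = truth["domain_spans"]
            group, subgroup = truth["group"], truth["subgroup"]
        cds = reverse_translate(protein, rng, p_opt)
        return _Gene(gid, species, gid, category, group, subgroup, vstr,
                     p_opt, protein, cds, spans, baseline,
                     category == "decoy")

    def make_copy(donor: _Gene, species: str, relation: str,
                  base_omega: float, base_ks: float) -> _Gene:
        omega = _coupled_omega(cfg, base_omega, donor.p_opt, donor.baseline)
        ks = _jittered_ks(cfg, base_ks, rng)
        (evolved,), truth = _evolve(
            donor.cds, omega, ks, rng, n_lineages=1,
            protected_codons=_protected_codons(donor.domain_spans),
            forbidden_new_aa=frozenset("WCH"), kappa=cfg.kappa,
        )
        gid = next_id(species)
        protein = "".join(
            GENETIC_CODE[evolved[i : i + 3]] for i in range(0, len(evolved), 3)
        )
        gene = _Gene(gid, species, donor.family, donor.category, donor.group,
                     donor.subgroup, donor.variant, donor.p_opt, protein,
                     evolved, donor.domain_spans, donor.baseline, False)
        pair_rows.append({
            "a": donor.id, "b": gid, "species_a": donor.species,
            "species_b": species, "relation": relation,
            "omega_planted": omega, "ks_planted": ks,
            "ks_realized": truth["realized_ks"],
            "ka_realized": truth["realized_ka"],
            "ratio_realized": truth["realized_ratio"],
            "syn_subs": truth["syn_subs"], "nonsyn_subs": truth["nonsyn_subs"],
            "divergent": False, "divergent_tissues": "", "effects": "",
        })
        return gene

    species_names = [f"sp{i + 1}" for i in range(cfg.n_species)]
    for si, species in enumerate(species_names):
        n_orth = 0
        if si > 0 and cfg.ortholog_fraction > 0:
            donors_pool = [g for g in genes if g.species == species_names[0]
                           and not g.is_decoy]
            n_orth = min(int(round(cfg.ortholog_fraction * cfg.genes_per_species)),
                         len(donors_pool))
            if n_orth:
                picked = rng.choice(len(donors_pool), size=n_orth, replace=False)
                for j in sorted(int(x) for x in picked):
                    genes.append(make_copy(donors_pool[j], species, "ortholog",
                                           cfg.ortholog_omega, cfg.ortholog_ks))
        counts = _allocate(cfg.composition, cfg.genes_per_species - n_orth)
        decoy_toggle = 0
        for category in sorted(counts):
            for _ in range(counts[category]):
                kind = ("no_hepta", "no_zf")[decoy_toggle % 2]
                if category == "decoy":
                    decoy_toggle += 1
                genes.append(make_fresh(species, category, kind))

    # Within-species duplicates (paralogs), one-sided evolution.
    paralog_pairs_start = len(pair_rows)
    for species in species_names:
        eligible = [g for g in genes if g.species == species and not g.is_decoy]
        n_dup = int(round(cfg.duplicate_fraction * len(eligible)))
        if not n_dup:
            continue
        picked = rng.choice(len(eligible), size=n_dup, replace=False)
        for j in sorted(int(x) for x in picked):
            genes.append(make_copy(eligible[j], species, "paralog",
                                   cfg.paralog_omega, cfg.paralog_ks))

    # Plant expression divergence on an exact count of the paralog pairs.
    paralog_idx = [i for i in range(paralog_pairs_start, len(pair_rows))
                   if pair_rows[i]["relation"] == "paralog"]
    n_divergent = int(round(cfg.divergence_fraction * len(paralog_idx)))
    divergence_plan: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if n_divergent:
        chosen = rng.choice(len(paralog_idx), size=n_divergent, replace=False)
        for j in sorted(int(x) for x in chosen):
            row = pair_rows[paralog_idx[j]]
            k = int(rng.integers(1, 4))
            tissue_ids = np.sort(rng.choice(len(tissues), size=min(k, len(tissues)),
                                            replace=False))
            effects = rng.uniform(*cfg.divergence_effect, size=len(tissue_ids))
            row["divergent"] = True
            row["divergent_tissues"] = ";".join(tissues[t] for t in tissue_ids)
            row["effects"] = ";".join(f"{e:.3f}" for e in effects)
            divergence_plan[row["b"]] = (tissue_ids, effects)

    expr_rows = []
    for gene in genes:
        noise = rng.normal(0.0, cfg.expr_noise_sd, size=len(tissues))
        values = gene.baseline * np.exp2(noise)
        if gene.id in divergence_plan:
            tissue_ids, effects = divergence_plan[gene.id]
            values[tissue_ids] *= np.exp2(effects)
        expr_rows.append(values)
    expression = pd.DataFrame(expr_rows, index=[g.id for g in genes],
                              columns=list(tissues))
    expression.index.name = "gene"

    duplicated = {r["a"] for r in pair_rows if r["relation"] == "paralog"}
    duplicated |= {r["b"] for r in pair_rows if r["relation"] == "paralog"}
    labels = pd.DataFrame([
        {
            "gene": g.id, "species": g.species, "family": g.family,
            "category": g.category, "group": g.group, "subgroup": g.subgroup,
            "n_domains": len(g.domain_spans), "variant": g.variant,
            "p_opt": g.p_opt, "is_decoy": g.is_decoy,
            "is_duplicate": g.id in duplicated,
        }
        for g in genes
    ]).set_index("gene")
    pairs = pd.DataFrame(pair_rows, columns=[
        "a", "b", "species_a", "species_b", "relation", "omega_planted",
        "ks_planted", "ks_realized", "ka_realized", "ratio_realized",
        "syn_subs", "nonsyn_subs", "divergent", "divergent_tissues", "effects",
    ])
    proteins = [ProteinRecord(g.id, g.protein, species=g.species) for g in genes]
    cds = [CdsRecord(g.id, g.cds, species=g.species) for g in genes]
    return CohortBundle(proteins, cds, expression, labels, pairs,
                        reference_set(), tissues, cfg)


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write a cohort bundle as FASTA/TSV files plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteins, outdir / "proteins.fasta")
    write_fasta(bundle.cds, outdir / "cds.fasta")
    write_expression(bundle.expression, outdir / "expression.tsv")
    bundle.labels.to_csv(outdir / "truth_labels.tsv", sep="\t")
    bundle.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    refs = [ProteinRecord(f"{label}_ref{i + 1}", seq)
            for label, seqs in sorted(bundle.references.references.items())
            for i, seq in enumerate(seqs)]
    write_fasta(refs, outdir / "references.fasta")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=2, default=str)
        fh.write("\n")
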