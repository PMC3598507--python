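"""Per-gene selection statistics from codon alignments.

The central quantity is a counting-based estimate of selective constraint:
the ratio of nonsynonymous to synonymous mutation *counts* in an alignment
of closely related strain sequences (pN/pS for within-species polymorphism,
dN/dS for two-sequence divergence).  Counts are deliberately not normalised
by mutational opportunity for pN/pS — the statistic is a raw tally, which is
adequate for ranking genes within one genome against each other.  dN/dS, in
contrast, uses Nei–Gojobori (1986) site counting with a Jukes–Cantor
multiple-hit correction, the standard counting estimator for close pairs.

Codons whose column contains a gap, an ambiguous base or a stop in any row
are excluded wholly, avoiding frame ambiguity.  Multi-step codon changes are
resolved by enumerating minimal mutational pathways, discarding pathways
through stop codons, and averaging — the NG86 convention.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from functools import cache, lru_cache
from itertools import combinations, permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial; identical to the
# standard code on all 61 sense codons, which is all this module uses
_FORWARD = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)

_BASES = "ACGT"
_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}
_STOP_IDX = frozenset(_CODON_INDEX[c] for c in STOP_CODONS)


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard (bacterial) genetic code.

    Returns a one-letter amino acid, or ``"*"`` for a stop codon.  Raises
    ``ValueError`` on ambiguous or illegal characters.
    """
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    if codon in STOP_CODONS:
        return "*"
    return _FORWARD[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


@dataclass(frozen=True)
class PathwayClassification:
    """Nonsynonymous/synonymous fractions for one codon change.

    For codons differing at 2 or 3 positions the fractions are averages over
    minimal mutational pathways, so they may be non-integer; they always sum
    to the Hamming distance between the codons (when at least one pathway
    avoids stop codons; otherwise all pathways are used as a fallback).
    """

    codon_a: str
    codon_b: str
    n_frac: float
    s_frac: float


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    aa_a = translate_codon(codon_a)
    aa_b = translate_codon(codon_b)
    if aa_a == "*" or aa_b == "*":
        raise ValueError("stop codons cannot be classified")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    everything: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = codon_a
        n = s = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if translate_codon(cur) == translate_codon(nxt):
                s += 1
            else:
                n += 1
            if is_stop(nxt):
                through_stop = True
            cur = nxt
        everything.append((n, s))
        if not through_stop:
            valid.append((n, s))
    chosen = valid if valid else everything
    n_frac = sum(p[0] for p in chosen) / len(chosen)
    s_frac = sum(p[1] for p in chosen) / len(chosen)
    return n_frac, s_frac


def classify_substitution(codon_a: str, codon_b: str) -> PathwayClassification:
    """Classify the change between two sense codons as N/S fractions.

    Single-step changes are classified directly by amino-acid identity;
    multi-step changes average over minimal mutational pathways, skipping
    pathways that pass through a stop codon (all pathways are used if every
    one passes through a stop).
    """
    n, s = _pathway_counts(codon_a.upper(), codon_b.upper())
    return PathwayClassification(codon_a.upper(), codon_b.upper(), n, s)


@cache
def _pair_tables() -> tuple[np.ndarray, np.ndarray]:
    """64x64 lookup of pathway-averaged (N, S) for sense-codon pairs."""
    n_tab = np.full((64, 64), np.nan)
    s_tab = np.full((64, 64), np.nan)
    for i, a in enumerate(_CODONS):
        if i in _STOP_IDX:
            continue
        for j, b in enumerate(_CODONS):
            if j in _STOP_IDX:
                continue
            n, s = _pathway_counts(a, b)
            n_tab[i, j] = n
            s_tab[i, j] = s
    return n_tab, s_tab


@cache
def _site_tables() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon NG86 nonsynonymous/synonymous site counts.

    For each sense codon and each of its three positions, the 3 single-base
    mutants are enumerated; mutants that are stop codons are excluded from
    the opportunity, and the position contributes the synonymous fraction of
    the remaining mutants to S (the rest to N).  Every position has at least
    one non-stop mutant, so N + S == 3 for every sense codon.
    """
    n_sites = np.full(64, np.nan)
    s_sites = np.full(64, np.nan)
    for i, codon in enumerate(_CODONS):
        if i in _STOP_IDX:
            continue
        aa = translate_codon(codon)
        n_tot = s_tot = 0.0
        for pos in range(3):
            syn = 0
            m = 0
            for base in _BASES:
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if is_stop(mut):
                    continue
                m += 1
                if translate_codon(mut) == aa:
                    syn += 1
            if m:
                s_tot += syn / m
                n_tot += (m - syn) / m
        n_sites[i] = n_tot
        s_sites[i] = s_tot
    return n_sites, s_sites


@dataclass
class SelectionEstimate:
    """One gene's N/S mutation counts and rate ratio.

    ``stat_kind`` is ``"polymorphism"`` (pN/pS) or ``"divergence"`` (dN/dS).
    ``s_corrected`` marks the pS→1 (or dS→1-style) zero-denominator rule.
    ``usable`` is False when the alignment carries no information (no
    retained columns, no differences, or a saturated divergence estimate).
    """

    gene_id: str
    genome_id: str
    stat_kind: str
    n_count: float
    s_count: float
    s_corrected: bool
    ratio: float
    n_codons_used: int
    n_rows: int
    usable: bool = True
    recombination_flagged: bool = False


def pnps(n_count: float, s_count: float) -> tuple[float, bool]:
    """Form the pN/pS ratio, approximating pS by 1 when it is zero.

    Returns ``(ratio, s_corrected)``; ``s_corrected`` is True iff the
    zero-synonymous-count correction was applied.
    """
    if n_count < 0 or s_count < 0:
        raise ValueError("mutation counts must be non-negative")
    if s_count == 0:
        return float(n_count), True
    return float(n_count) / float(s_count), False


# -- alignment encoding -----------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def _encode(rows: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode rows as codon indices and a retained-column mask.

    Returns ``(codon_idx, retained, valid_base)`` where ``codon_idx`` is
    ``(n_rows, n_codons)`` with -1 for codons containing non-ACGT symbols,
    ``retained`` marks codon columns free of gaps/ambiguity/stops in every
    row, and ``valid_base`` is the per-site ACGT mask used by the
    recombination screen.
    """
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr].reshape(len(rows), -1)
    n_codons = codes.shape[1] // 3
    cod = codes.reshape(len(rows), n_codons, 3)
    valid = (cod != 255).all(axis=2)
    idx = (cod[:, :, 0].astype(np.int64) * 16
           + cod[:, :, 1].astype(np.int64) * 4
           + cod[:, :, 2].astype(np.int64))
    idx[~valid] = -1
    stop_arr = np.zeros(64, dtype=bool)
    for s in _STOP_IDX:
        stop_arr[s] = True
    is_stop_col = np.zeros_like(valid)
    is_stop_col[valid] = stop_arr[idx[valid]]
    retained = valid.all(axis=0) & ~is_stop_col.any(axis=0)
    return idx, retained, codes != 255


def count_gene_polymorphisms(aln) -> SelectionEstimate:
    """Count nonsynonymous/synonymous polymorphisms in a strain alignment.

    Codon columns containing a gap, 'N' or stop codon in any row are
    excluded.  With two rows, differing codons are classified directly.
    With more rows, the majority codon of each column (ties resolved to the
    reference row's codon) is taken as the base state and each distinct
    variant codon is classified against it once — allele counting, so
    duplicated rows do not inflate the counts.
    """
    if len(aln.rows) < 2:
        raise ValueError("polymorphism counting needs at least 2 rows")
    idx, retained, _ = _encode(aln.rows)
    n_used = int(retained.sum())
    genome = aln.genome_ids[aln.reference_row]
    if n_used == 0:
        return SelectionEstimate(aln.gene_id, genome, "polymorphism",
                                 0.0, 0.0, True, 0.0, 0, len(aln.rows),
                                 usable=False)
    n_tab, s_tab = _pair_tables()
    if len(aln.rows) == 2:
        a = idx[0][retained]
        b = idx[1][retained]
        m = a != b
        n_count = float(n_tab[a[m], b[m]].sum()) if m.any() else 0.0
        s_count = float(s_tab[a[m], b[m]].sum()) if m.any() else 0.0
    else:
        n_count = s_count = 0.0
        cols = np.nonzero(retained)[0]
        for j in cols:
            col = idx[:, j]
            if (col == col[0]).all():
                continue
            counts = Counter(int(c) for c in col)
            top = max(counts.values())
            tied = sorted(c for c, k in counts.items() if k == top)
            ref_codon = int(col[aln.reference_row])
            base = ref_codon if ref_codon in tied else tied[0]
            for variant in sorted(set(int(c) for c in col) - {base}):
                n_count += float(n_tab[base, variant])
                s_count += float(s_tab[base, variant])
    ratio, corrected = pnps(n_count, s_count)
    usable = (n_count + s_count) > 0
    return SelectionEstimate(aln.gene_id, genome, "polymorphism",
                             n_count, s_count, corrected, ratio,
                             n_used, len(aln.rows), usable=usable)


def _jukes_cantor(p: float) -> float:
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def dnds_ng86(aln) -> SelectionEstimate:
    """Nei–Gojobori (1986) dN/dS for a two-sequence alignment.

    Site counts use per-codon enumeration of the nine single-base changes
    with stop mutants excluded from the opportunity; observed differences
    are classified via pathway averaging; both proportions receive the
    Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3).  A proportion ≥ 3/4 is
    saturated and the estimate is flagged unusable (ratio NaN).  When no
    synonymous differences are observed the ratio falls back to the
    uncorrected nonsynonymous proportion over a unit denominator, with the
    ``s_corrected`` flag set — the divergence analogue of the pS→1 rule.
    """
    if len(aln.rows) != 2:
        raise ValueError("dN/dS estimation requires exactly 2 rows")
    idx, retained, _ = _encode(aln.rows)
    n_used = int(retained.sum())
    genome = aln.genome_ids[aln.reference_row]

    def estimate(n, s, corrected, ratio, usable):
        return SelectionEstimate(aln.gene_id, genome, "divergence",
                                 n, s, corrected, ratio, n_used,
                                 2, usable=usable)

    if n_used == 0:
        return estimate(0.0, 0.0, True, 0.0, False)
    a = idx[0][retained]
    b = idx[1][retained]
    n_sites_tab, s_sites_tab = _site_tables()
    n_sites = float((n_sites_tab[a].sum() + n_sites_tab[b].sum()) / 2.0)
    s_sites = float((s_sites_tab[a].sum() + s_sites_tab[b].sum()) / 2.0)
    n_tab, s_tab = _pair_tables()
    m = a != b
    nd = float(n_tab[a[m], b[m]].sum()) if m.any() else 0.0
    sd = float(s_tab[a[m], b[m]].sum()) if m.any() else 0.0
    if nd + sd == 0:
        return estimate(0.0, 0.0, True, 0.0, False)
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    if pn >= 0.75 or ps >= 0.75:
        logger.warning("gene %s: saturated divergence (pN*=%.3f pS*=%.3f)",
                       aln.gene_id, pn, ps)
        return estimate(nd, sd, False, float("nan"), False)
    dn = _jukes_cantor(pn)
    ds = _jukes_cantor(ps)
    if sd == 0:
        return estimate(nd, sd, True, pn, True)
    return estimate(nd, sd, False, dn / ds, True)


def four_gamete_screen(aln) -> tuple[int, bool]:
    """Four-gamete recombination screen over biallelic nucleotide sites.

    Counts pairs of biallelic sites (sites with exactly two distinct
    unambiguous bases across rows and no gaps) that exhibit all four
    haplotype combinations; any such pair implies recombination or
    recurrent mutation.  With fewer than 4 rows the test cannot trigger and
    ``(0, False)`` is returned.
    """
    if len(aln.rows) < 4:
        return 0, False
    arr = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr].reshape(len(aln.rows), -1)
    ok = (codes != 255).all(axis=0)
    biallelic_cols = []
    for j in np.nonzero(ok)[0]:
        col = codes[:, j]
        uniq = np.unique(col)
        if uniq.size == 2:
            biallelic_cols.append(col == uniq[0])
    violations = 0
    for x, y in combinations(biallelic_cols, 2):
        gametes = {(bool(p), bool(q)) for p, q in zip(x, y)}
        if len(gametes) == 4:
            violations += 1
    return violations, violations > 0


def estimates_to_frame(estimates: Iterable[SelectionEstimate]) -> pd.DataFrame:
    """Tabulate estimates with the columns of the per-gene TSV interface."""
    cols = ["gene_id", "genome_id", "stat_kind", "n_count", "s_count",
            "s_corrected", "ratio", "n_codons_used", "n_rows", "usable",
            "recombination_flagged"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in estimates],
                        columns=cols)


__all__ = [
    "PathwayClassification", "SelectionEstimate", "STOP_CODONS",
    "translate_codon", "is_stop", "classify_substitution", "pnps",
    "count_gene_polymorphisms", "dnds_ng86", "four_gamete_screen",
    "estimates_to_frame",
]
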