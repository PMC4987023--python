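"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from turnoverlab.alleles import AllelePanel, DonorGenotype


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no turnoverlab internals)
# ---------------------------------------------------------------------------


def naive_digest(seq: str, max_missed: int, min_len: int, max_len: int):
    """Brute-force tryptic digest: enumerate all fragments between cleavage
    boundaries (after K/R not followed by P) spanning <= max_missed sites."""
    cuts = [0]
    cuts += [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    cuts.append(len(seq))
    peps = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(cuts))):
            s, e = cuts[i], cuts[j]
            if min_len <= e - s <= max_len:
                peps.append((s + 1, e, seq[s:e], j - i - 1))
    return peps


def brute_classify(
    entries: dict[str, str],
    locus_of: dict[str, str],
    alleles: list[str],
    max_missed: int,
    min_len: int,
    max_len: int,
    il_equivalent: bool = False,
):
    """Set-membership classification over naive digests."""
    key = (lambda s: s.replace("I", "L")) if il_equivalent else (lambda s: s)
    digests = {
        a: {key(p) for _, _, p, _ in naive_digest(entries[a], max_missed, min_len, max_len)}
        for a in alleles
    }
    per_locus: dict[str, set[str]] = {}
    for a in alleles:
        per_locus.setdefault(locus_of[a], set()).add(a)
    result = {}
    for pep in set().union(*digests.values()):
        carriers = frozenset(a for a in alleles if pep in digests[a])
        loci = {locus_of[a] for a in carriers}
        if len(loci) > 1:
            cat = "ambiguous"
        elif len(carriers) == 1 and len(per_locus[next(iter(loci))]) > 1:
            cat = "allele_specific"
        else:
            cat = "isotype_specific"
        result[pep] = (cat, carriers)
    return result


def enumerate_isotopologues(counts: dict[str, int], table: dict) -> np.ndarray:
    """Exhaustive isotopologue enumeration for tiny molecules: product of
    per-atom abundances grouped by total mass offset."""
    atom_tables = []
    for el, n in counts.items():
        atom_tables.extend([table[el]] * n)
    max_off = sum(max(o for o, _ in t) for t in atom_tables) if atom_tables else 0
    out = np.zeros(max_off + 1)
    for combo in itertools.product(*atom_tables):
        off = sum(o for o, _ in combo)
        prob = math.prod(a for _, a in combo)
        out[off] += prob
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_panel():
    """Hand-built panel in which each specificity category is forced.

    Peptides (digest with min_len=4, max_len=30, max_missed=0):
      - "LTTTTK"  only in A1                         -> allele_specific
      - "GGGDDDK" in A1 and A2                       -> isotype_specific (A)
      - "WWHHFFK" in C1 and A2                       -> ambiguous
      - "MEEEER"  only in C1 (homozygous locus C)    -> isotype_specific (C)
    """
    entries = {
        "A1": "GGGDDDKLTTTTKAAAWWR",
        "A2": "GGGDDDKWWHHFFKAAAWWR",
        "C1": "MEEEERWWHHFFK",
    }
    locus_of = {"A1": "A", "A2": "A", "C1": "C"}
    panel = AllelePanel(entries=entries, locus_of=locus_of)
    genotype = DonorGenotype("toy", ("A1", "A2", "C1"))
    return panel, genotype
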