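"""Mass isotopomer distribution analysis (MIDA) for heavy-water labeling.

Even without isotopic labeling, a peptide ion appears in the mass spectrum
as an envelope of "mass isotopomers" m0, m1, m2, ... — species differing
only in their total count of heavy isotopes — because stable isotopes are
incorporated at natural abundance, dominantly 13C (1.09 % of natural
carbon). During 2H2O labeling, deuterium enters C-H bonds of nonessential
amino acids during protein synthesis, so newly made protein carries extra
label at ``n`` effective incorporation sites, each enriched to the body- or
media-water enrichment ``p`` (about 5 % in the cell-culture design this
package models). The labeled envelope is therefore the natural envelope
convolved with Binomial(n, p).

Because old (unlabeled) and new (labeled) protein mix linearly, an
intermediate envelope is a weighted average of the unlabeled baseline and
the fully-labeled plateau, with weight equal to the fraction ``f`` of newly
synthesized protein. ``f`` is quantified per mass isotopomer as the
fractional shift from baseline toward plateau, averaged over the channels
whose baseline-to-plateau difference is large enough to be informative.

Conventions
-----------
* The measured media enrichment is treated as *excess* enrichment above
  natural deuterium; natural 2H (0.0115 %) at labeled sites is ignored
  (relative error below 0.3 % at p = 0.05), since the unlabeled baseline
  already absorbs it.
* ``n`` is an integer count of exchangeable C-H positions; the site fit is
  an integer grid search, ties broken toward smaller ``n``.
* Envelopes are truncated to a finite number of channels and renormalized
  to sum exactly to 1; the default truncation keeps >= 99.9 % of the
  cumulative abundance, capped at 10 channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from pyteomics import mass as _pyt_mass
from scipy import stats

from .alleles import check_sequence
from .errors import FitError, UnquantifiablePeptideError

__all__ = [
    "ElementalComposition",
    "IsotopeTable",
    "DEFAULT_ISOTOPE_TABLE",
    "MassIsotopomerDistribution",
    "MIDAFit",
    "FractionalSynthesisPoint",
    "QCCriteria",
    "composition_of",
    "natural_distribution",
    "labeled_distribution",
    "distribution_rmsd",
    "fit_incorporation_sites",
    "fit_plateau_mixture",
    "fractional_synthesis",
    "qc_filter",
]

MAX_CHANNELS_DEFAULT = 10
TRUNCATION_COVERAGE = 0.999


@dataclass(frozen=True)
class ElementalComposition:
    """Elemental composition of a neutral peptide, fixed mods included."""

    C: int
    H: int
    N: int
    O: int
    S: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O", "S"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")
        if self.H < 2 or self.O < 1:
            raise ValueError(
                "peptide composition must include terminal water (H>=2, O>=1)"
            )

    def as_dict(self) -> dict[str, int]:
        return {"C": self.C, "H": self.H, "N": self.N, "O": self.O, "S": self.S}


#: Natural isotope abundances as (mass-number offset, fraction) per element.
#: The heavy-carbon value is 0.0109 (1.09 % of natural carbon); the rest are
#: standard terrestrial abundances. Fully overridable via IsotopeTable.
_DEFAULT_ABUNDANCES: dict[str, tuple[tuple[int, float], ...]] = {
    "H": ((0, 0.999885), (1, 0.000115)),
    "C": ((0, 0.9891), (1, 0.0109)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
}


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope distributions over unit-mass offsets."""

    abundances: Mapping[str, tuple[tuple[int, float], ...]]

    def __post_init__(self) -> None:
        for el, pairs in self.abundances.items():
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"isotope abundances for {el} sum to {total!r}, not 1"
                )
            for off, a in pairs:
                if not (0.0 <= a <= 1.0) or off < 0:
                    raise ValueError(f"invalid isotope entry for {el}: {(off, a)}")

    def element_array(self, element: str) -> np.ndarray:
        """Abundance array indexed by mass offset for one element."""
        pairs = self.abundances[element]
        arr = np.zeros(max(off for off, _ in pairs) + 1)
        for off, a in pairs:
            arr[off] += a
        return arr


DEFAULT_ISOTOPE_TABLE = IsotopeTable(abundances=_DEFAULT_ABUNDANCES)


@dataclass(frozen=True)
class MassIsotopomerDistribution:
    """Fractional abundances of mass isotopomers m0..mK, summing to 1."""

    channels: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("channels must be a non-empty 1-D sequence")
        if np.any(arr < 0):
            raise ValueError("channel abundances must be non-negative")

    @staticmethod
    def from_raw(raw: Sequence[float]) -> "MassIsotopomerDistribution":
        """Normalize raw (e.g. integrated ion) abundances to fractions."""
        arr = np.asarray(raw, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("total abundance must be positive")
        return MassIsotopomerDistribution(channels=tuple(arr / total))

    @property
    def k_max(self) -> int:
        return len(self.channels) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.channels, dtype=float)


# ---------------------------------------------------------------------------
# Elemental composition
# ---------------------------------------------------------------------------

_CARBAMIDOMETHYL = {"C": 2, "H": 3, "N": 1, "O": 1, "S": 0}


def composition_of(
    peptide: str,
    cys_carbamidomethyl: bool = True,
    met_oxidized_count: int = 0,
) -> ElementalComposition:
    """Elemental composition of a neutral tryptic peptide.

    Residue formulas plus one terminal water; carbamidomethylation
    (+C2H3NO per Cys) is applied as a fixed modification when
    ``cys_carbamidomethyl`` is set, and each oxidized Met adds one O.
    """
    check_sequence(peptide, context="peptide")
    if met_oxidized_count < 0 or met_oxidized_count > peptide.count("M"):
        raise ValueError(
            "met_oxidized_count must be between 0 and the number of M residues"
        )
    comp = _pyt_mass.Composition(sequence=peptide)
    counts = {el: int(comp.get(el, 0)) for el in ("C", "H", "N", "O", "S")}
    if cys_carbamidomethyl:
        n_cys = peptide.count("C")
        for el, k in _CARBAMIDOMETHYL.items():
            counts[el] += k * n_cys
    counts["O"] += met_oxidized_count
    return ElementalComposition(**counts)


# ---------------------------------------------------------------------------
# Isotopomer envelopes
# ---------------------------------------------------------------------------


def _convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation."""
    result = np.array([1.0])
    base = dist
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


#: Compositions may be given as :class:`ElementalComposition` (peptides) or
#: as a bare element->count mapping (arbitrary molecules, e.g. in tests).
CompositionLike = "ElementalComposition | Mapping[str, int]"


def _counts_of(comp) -> tuple[tuple[str, int], ...]:
    if isinstance(comp, ElementalComposition):
        d = comp.as_dict()
    else:
        d = {el: int(n) for el, n in dict(comp).items()}
        if any(n < 0 for n in d.values()):
            raise ValueError("element counts must be >= 0")
    return tuple(sorted((el, n) for el, n in d.items() if n > 0))


def _hydrogen_count(comp) -> int:
    return dict(_counts_of(comp)).get("H", 0)


def _full_envelope(
    counts: tuple[tuple[str, int], ...], table: IsotopeTable
) -> np.ndarray:
    out = np.array([1.0])
    for el, count in counts:
        out = np.convolve(out, _convolve_power(table.element_array(el), count))
    return out


@lru_cache(maxsize=4096)
def _full_envelope_default(counts: tuple[tuple[str, int], ...]) -> np.ndarray:
    env = _full_envelope(counts, DEFAULT_ISOTOPE_TABLE)
    env.setflags(write=False)
    return env


def _envelope(comp, table: IsotopeTable | None) -> np.ndarray:
    counts = _counts_of(comp)
    if table is None or table is DEFAULT_ISOTOPE_TABLE:
        return _full_envelope_default(counts)
    return _full_envelope(counts, table)


def _truncate_normalize(env: np.ndarray, k_max: int) -> MassIsotopomerDistribution:
    trunc = env[: k_max + 1]
    if trunc.size < k_max + 1:
        trunc = np.pad(trunc, (0, k_max + 1 - trunc.size))
    return MassIsotopomerDistribution(channels=tuple(trunc / trunc.sum()))


def auto_k_max(
    comp: ElementalComposition,
    table: IsotopeTable | None = None,
    coverage: float = TRUNCATION_COVERAGE,
    cap: int = MAX_CHANNELS_DEFAULT,
) -> int:
    """Smallest K such that channels m0..mK retain *coverage* of the natural
    envelope, capped at *cap* channels (K = cap - 1)."""
    env = _envelope(comp, table)
    cum = np.cumsum(env)
    k = int(np.searchsorted(cum, coverage))
    return max(1, min(k, cap - 1))


def auto_k_max_labeled(
    comp: ElementalComposition,
    n_sites: int,
    enrichment_p: float,
    table: IsotopeTable | None = None,
    coverage: float = TRUNCATION_COVERAGE,
    cap: int = MAX_CHANNELS_DEFAULT,
) -> int:
    """Like :func:`auto_k_max`, but for the fully-labeled envelope, whose
    mass distribution is shifted upward by the incorporated deuterium."""
    env = np.array(_envelope(comp, table))
    if n_sites > 0 and enrichment_p > 0.0:
        label = stats.binom.pmf(np.arange(n_sites + 1), n_sites, enrichment_p)
        env = np.convolve(env, label)
    cum = np.cumsum(env)
    k = int(np.searchsorted(cum, coverage))
    return max(1, min(k, cap - 1))


def natural_distribution(
    comp: ElementalComposition,
    table: IsotopeTable | None = None,
    k_max: int | None = None,
) -> MassIsotopomerDistribution:
    """Natural-abundance mass isotopomer distribution of *comp*.

    The envelope is the convolution of per-atom isotope distributions over
    all atoms, truncated at ``k_max`` and renormalized.
    """
    if k_max is None:
        k_max = auto_k_max(comp, table)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return _truncate_normalize(np.array(_envelope(comp, table)), k_max)


def labeled_distribution(
    comp: ElementalComposition,
    n_sites: int,
    enrichment_p: float,
    table: IsotopeTable | None = None,
    k_max: int | None = None,
) -> MassIsotopomerDistribution:
    """Fully-labeled envelope: natural envelope convolved with
    Binomial(``n_sites``, ``enrichment_p``) excess-deuterium incorporation.
    """
    if not (0.0 <= enrichment_p < 1.0):
        raise ValueError("enrichment_p must be in [0, 1)")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    n_h = _hydrogen_count(comp)
    if n_sites > n_h:
        raise ValueError(
            f"n_sites={n_sites} exceeds the {n_h} hydrogens of the molecule"
        )
    if k_max is None:
        k_max = auto_k_max(comp, table)
    env = np.array(_envelope(comp, table))
    if n_sites > 0 and enrichment_p > 0.0:
        label = stats.binom.pmf(np.arange(n_sites + 1), n_sites, enrichment_p)
        env = np.convolve(env, label)
    return _truncate_normalize(env, k_max)


def distribution_rmsd(
    a: MassIsotopomerDistribution | Sequence[float],
    b: MassIsotopomerDistribution | Sequence[float],
) -> float:
    """Root-mean-square deviation between two envelopes.

    The shorter envelope is zero-padded; the result is symmetric.
    """
    x = a.as_array() if isinstance(a, MassIsotopomerDistribution) else np.asarray(a, float)
    y = b.as_array() if isinstance(b, MassIsotopomerDistribution) else np.asarray(b, float)
    k = max(x.size, y.size)
    x = np.pad(x, (0, k - x.size))
    y = np.pad(y, (0, k - y.size))
    return float(np.sqrt(np.mean((x - y) ** 2)))


# ---------------------------------------------------------------------------
# Fitting the number of incorporation sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MIDAFit:
    """Result of fitting the effective number of 2H incorporation sites.

    ``runnerup_margin`` is the relative RMSD separation between the best
    and second-best candidate ``n``: a small margin means adjacent site
    counts explain the data equally well, so the plateau model (and any
    fractional synthesis computed against it) is ill-determined.
    """

    n_sites: int
    enrichment_p: float
    rmsd: float
    baseline_model: MassIsotopomerDistribution
    plateau_model: MassIsotopomerDistribution
    runnerup_margin: float = float("inf")

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        if not (0.0 <= self.enrichment_p <= 1.0):
            raise ValueError("enrichment_p must be in [0, 1]")


def _check_n_range(n_range: tuple[int, int], comp) -> range:
    lo, hi = n_range
    if lo > hi:
        raise FitError(f"empty n_range {n_range}")
    n_h = _hydrogen_count(comp)
    if lo < 0 or hi > n_h:
        raise FitError(
            f"n_range {n_range} outside [0, {n_h}] (molecule hydrogens)"
        )
    return range(lo, hi + 1)


def fit_incorporation_sites(
    observed_plateau: MassIsotopomerDistribution,
    comp: ElementalComposition,
    enrichment_p: float,
    n_range: tuple[int, int],
    table: IsotopeTable | None = None,
) -> MIDAFit:
    """Fit ``n`` to a measured fully-labeled (plateau) envelope.

    Scans the integer grid ``n_range`` (inclusive) and returns the ``n``
    whose labeled model minimizes the RMSD against the observation; ties go
    to the smaller ``n``.
    """
    k_max = observed_plateau.k_max
    obs = observed_plateau.as_array()
    best_n, best_rmsd, best_model, second = None, np.inf, None, np.inf
    for n in _check_n_range(n_range, comp):
        model = labeled_distribution(comp, n, enrichment_p, table, k_max)
        r = distribution_rmsd(model.as_array(), obs)
        if r < best_rmsd:
            best_n, best_rmsd, best_model, second = n, r, model, best_rmsd
        elif r < second:
            second = r
    return MIDAFit(
        n_sites=best_n,
        enrichment_p=enrichment_p,
        rmsd=best_rmsd,
        baseline_model=natural_distribution(comp, table, k_max),
        plateau_model=best_model,
        runnerup_margin=_margin(best_rmsd, second),
    )


def _margin(best: float, second: float) -> float:
    if not np.isfinite(second):
        return float("inf")
    if best <= 0.0:
        return float("inf") if second > 0 else 0.0
    return (second - best) / best


def fit_plateau_mixture(
    observed: MassIsotopomerDistribution | Sequence[MassIsotopomerDistribution],
    comp: ElementalComposition,
    enrichment_p: float,
    n_range: tuple[int, int],
    table: IsotopeTable | None = None,
) -> tuple[MIDAFit, np.ndarray]:
    """Jointly fit ``n`` and per-observation labeled fractions.

    Used when no true plateau sample exists (label duration shorter than
    several half-lives): each observed envelope is modeled as
    ``(1 - lam_t) * baseline + lam_t * labeled(n)`` with one shared ``n``
    and, per candidate ``n``, closed-form least-squares mixing fractions
    ``lam_t`` (clipped to [0, 1]). Fitting across the whole time course —
    rather than the last sample only — pins ``n`` down with all the label
    information available. Returns the best fit (ties toward smaller ``n``)
    and the array of mixing fractions; the reported RMSD pools residuals
    over all observations.
    """
    obs_list = (
        [observed]
        if isinstance(observed, MassIsotopomerDistribution)
        else list(observed)
    )
    k_max = obs_list[0].k_max
    if any(o.k_max != k_max for o in obs_list):
        raise ValueError("all observations must have equal channel counts")
    obs = np.stack([o.as_array() for o in obs_list])
    baseline = natural_distribution(comp, table, k_max)
    b = baseline.as_array()
    best: tuple[float, int, np.ndarray, MassIsotopomerDistribution] | None = None
    second = np.inf
    for n in _check_n_range(n_range, comp):
        model = labeled_distribution(comp, n, enrichment_p, table, k_max)
        d = model.as_array() - b
        denom = float(d @ d)
        if denom > 0:
            lam = np.clip((obs - b) @ d / denom, 0.0, 1.0)
        else:
            lam = np.zeros(obs.shape[0])
        resid = obs - b - lam[:, None] * d
        r = float(np.sqrt(np.mean(resid**2)))
        if best is None or r < best[0] - 1e-15:
            second = best[0] if best is not None else np.inf
            best = (r, n, lam, model)
        elif r < second:
            second = r
    rmsd, n_best, lam_best, model_best = best
    fit = MIDAFit(
        n_sites=n_best,
        enrichment_p=enrichment_p,
        rmsd=rmsd,
        baseline_model=baseline,
        plateau_model=model_best,
        runnerup_margin=_margin(rmsd, second),
    )
    return fit, lam_best


# ---------------------------------------------------------------------------
# Fractional synthesis
# ---------------------------------------------------------------------------

#: Channels whose baseline-to-plateau abundance difference is below this
#: (absolute fractional abundance) give poor estimates of f and are skipped.
DEFAULT_MIN_SHIFT = 0.08


@dataclass(frozen=True)
class FractionalSynthesisPoint:
    """Fractional synthesis at one time point, with per-channel spread."""

    f: float
    sd: float
    n_informative: int
    time_h: float | None = None
    qc_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_informative < 1:
            raise ValueError("a reported point needs >= 1 informative channel")


def fractional_synthesis(
    observed_t: MassIsotopomerDistribution,
    baseline: MassIsotopomerDistribution,
    plateau: MassIsotopomerDistribution,
    min_shift: float = DEFAULT_MIN_SHIFT,
    time_h: float | None = None,
) -> FractionalSynthesisPoint:
    """Fraction of newly synthesized protein from one observed envelope.

    For each channel whose baseline-to-plateau shift is at least
    ``min_shift`` in absolute fractional abundance, the per-channel estimate
    is ``(observed - baseline) / (plateau - baseline)``; the point estimate
    is their unweighted mean and ``sd`` their standard deviation (the
    analytical error of the point). Channels below ``min_shift`` are
    excluded as uninformative.

    Raises
    ------
    UnquantifiablePeptideError
        If no channel shifts by at least ``min_shift``.
    """
    if min_shift <= 0:
        raise ValueError("min_shift must be > 0")
    if not (
        observed_t.k_max == baseline.k_max == plateau.k_max
    ):
        raise ValueError("channel counts of all three envelopes must match")
    obs, b, p = observed_t.as_array(), baseline.as_array(), plateau.as_array()
    shift = p - b
    informative = np.abs(shift) >= min_shift
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise UnquantifiablePeptideError(
            f"no mass isotopomer shifts by >= {min_shift} between baseline "
            "and plateau; peptide is unquantifiable"
        )
    f_i = (obs[informative] - b[informative]) / shift[informative]
    f = float(np.mean(f_i))
    sd = float(np.std(f_i, ddof=1)) if n_inf > 1 else 0.0
    flags = set()
    # flag points implying f meaningfully outside [0, 1] given their noise
    # (small epsilon absorbs floating-point round-off at exact boundaries)
    if abs(f - 0.5) > 0.5 + 5.0 * sd + 1e-9:
        flags.add("f_out_of_range")
    return FractionalSynthesisPoint(
        f=f, sd=sd, n_informative=n_inf, time_h=time_h,
        qc_flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCCriteria:
    """Thresholds for excluding peptides/points liable to yield poor f.

    Defaults: total ion abundance >= 1e5 (instrument arbitrary units),
    plateau-model RMSD <= 0.01 (fractional abundance), per-point SD <= 0.15,
    and a site-fit identifiability requirement: the best candidate ``n``
    must beat the runner-up by >= 5 % relative RMSD, else the plateau model
    is considered ambiguous and the peptide unquantifiable.
    """

    min_total_abundance: float = 1e5
    max_plateau_rmsd: float = 0.01
    max_point_sd: float = 0.15
    min_plateau_margin: float = 0.05


@dataclass(frozen=True)
class QCRejection:
    point: FractionalSynthesisPoint
    reason: str


def qc_filter(
    series: Sequence[FractionalSynthesisPoint],
    criteria: QCCriteria,
    total_ion_abundance: float | None = None,
    plateau_rmsd: float | None = None,
    plateau_margin: float | None = None,
) -> tuple[list[FractionalSynthesisPoint], list[QCRejection]]:
    """Partition a peptide's time series into retained and rejected points.

    Peptide-level failures (low total ion abundance, poor plateau-model
    agreement, ambiguous site fit) reject every point; point-level failures
    (high SD, out-of-range f) reject individual points. Every rejection
    carries a machine-readable reason code.
    """
    if total_ion_abundance is not None and (
        total_ion_abundance < criteria.min_total_abundance
    ):
        return [], [QCRejection(pt, "low_abundance") for pt in series]
    if plateau_rmsd is not None and plateau_rmsd > criteria.max_plateau_rmsd:
        return [], [QCRejection(pt, "high_rmsd") for pt in series]
    if plateau_margin is not None and plateau_margin < criteria.min_plateau_margin:
        return [], [QCRejection(pt, "ambiguous_plateau") for pt in series]
    retained, rejected = [], []
    for pt in series:
        if pt.sd > criteria.max_point_sd:
            rejected.append(QCRejection(pt, "high_sd"))
        elif "f_out_of_range" in pt.qc_flags:
            rejected.append(QCRejection(pt, "f_out_of_range"))
        else:
            retained.append(pt)
    return retained, rejected
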