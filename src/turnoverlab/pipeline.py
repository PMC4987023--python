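"""End-to-end turnover analysis: classify -> MIDA -> kinetics -> report.

Runs the complete analysis on one labeling experiment:

1. digest the donor's allele sequences and classify peptides by
   specificity; ambiguous peptides (shared across loci) are logged and
   dropped — their signal cannot be attributed to one molecule;
2. for each quantified peptide, fit the MIDA model (number of
   incorporation sites) and compute fractional synthesis per time point;
3. apply quality-control filters;
4. fit single-exponential kinetics per peptide, test rate equality within
   each locus by extra-sum-of-squares F test, and report pooled per-isotype
   rates (primary when the F test does not reject pooling);
5. fit cell growth and convert synthesis rates to growth-corrected
   turnover half-lives.

Everything is deterministic given identical inputs, and rerunning
:func:`write_report` on the same report overwrites files byte-identically.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import alleles as _al
from . import kinetics as _kin
from . import mida as _mida
from .errors import ConfigError, TurnoverLabError, UnquantifiablePeptideError

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "TurnoverReport",
    "run_turnover_pipeline",
    "run_on_frames",
    "write_report",
]

_FLOAT_FMT = "%.10g"
_M_COL = re.compile(r"^m(\d+)$")


@dataclass(frozen=True)
class PipelineParams:
    """All analysis knobs, with their defaults."""

    enrichment_p: float = 0.05
    max_missed: int = _al.DEFAULT_MAX_MISSED
    min_len: int = _al.DEFAULT_MIN_LEN
    max_len: int = _al.DEFAULT_MAX_LEN
    il_equivalent: bool = False
    min_shift: float = _mida.DEFAULT_MIN_SHIFT
    n_range: tuple[int, int] = (0, 60)
    #: "model": theoretical natural baseline; "measured": observed t=0 rows.
    baseline_mode: Literal["model", "measured"] = "model"
    #: "mixture": jointly fit n and the labeled fraction on the last time
    #: point (no plateau sample required); "latest": treat the last time
    #: point as a fully-labeled plateau sample.
    plateau_mode: Literal["mixture", "latest"] = "mixture"
    qc: _mida.QCCriteria = field(default_factory=_mida.QCCriteria)
    alpha: float = 0.05
    weighting: _kin.Weighting = "none"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if not (0.0 <= self.enrichment_p < 1.0):
            raise ConfigError("enrichment_p must be in [0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    """File-based pipeline run configuration."""

    fasta: Path
    genotype: Path
    quant: Path
    counts: Path
    out_dir: Path | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        for name in ("fasta", "genotype", "quant", "counts"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} file does not exist: {p}")
        self.params.validate()


@dataclass
class TurnoverReport:
    """Tables produced by one pipeline run."""

    peptide_fits: pd.DataFrame
    group_fits: pd.DataFrame
    comparisons: pd.DataFrame
    turnover: pd.DataFrame
    mida_fits: pd.DataFrame
    exclusions: pd.DataFrame
    growth: _kin.GrowthFit
    params: PipelineParams


def _read_genotype(path: Path) -> _al.DonorGenotype:
    df = pd.read_csv(path)
    if not {"donor_id", "allele"} <= set(df.columns):
        raise ConfigError(
            f"genotype file {path} needs columns donor_id, allele"
        )
    donors = df["donor_id"].unique()
    if len(donors) != 1:
        raise ConfigError("genotype file must describe exactly one donor")
    return _al.DonorGenotype(str(donors[0]), tuple(df["allele"]))


def _m_columns(quant: pd.DataFrame) -> list[str]:
    cols = sorted(
        (c for c in quant.columns if _M_COL.match(c)),
        key=lambda c: int(_M_COL.match(c).group(1)),
    )
    if not cols:
        raise ConfigError("quant table has no m0..mK abundance columns")
    return cols


def _series_key(peptide: str, charge) -> str:
    return f"{peptide}/{int(charge)}+"


def run_turnover_pipeline(config: PipelineConfig) -> TurnoverReport:
    """Run the full analysis from files; write a report if out_dir is set."""
    config.validate()
    quant = pd.read_csv(config.quant)
    counts = pd.read_csv(config.counts)
    panel = _al.load_allele_sequences(config.fasta)
    genotype = _read_genotype(Path(config.genotype))
    report = run_on_frames(panel, genotype, quant, counts, config.params)
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def run_on_frames(
    panel: _al.AllelePanel,
    genotype: _al.DonorGenotype,
    quant: pd.DataFrame,
    counts: pd.DataFrame,
    params: PipelineParams | None = None,
) -> TurnoverReport:
    """Run the full analysis on in-memory inputs."""
    params = params or PipelineParams()
    params.validate()

    assignments = _al.classify_peptides(
        panel,
        genotype,
        max_missed=params.max_missed,
        min_len=params.min_len,
        max_len=params.max_len,
        il_equivalent=params.il_equivalent,
    )
    key_of = _al.collapse_il if params.il_equivalent else (lambda s: s)
    assignment_by_key = {key_of(a.peptide_sequence): a for a in assignments}

    mcols = _m_columns(quant)
    exclusions: list[dict] = []
    mida_rows: list[dict] = []
    peptide_series: list[tuple[_al.SpecificityAssignment, _kin.FractionalSynthesisSeries]] = []

    grouped = sorted(
        quant.groupby(["peptide", "charge"], sort=True),
        key=lambda kv: (kv[0][0], kv[0][1]),
    )
    for (peptide, charge), rows in grouped:
        label = _series_key(peptide, charge)
        assignment = assignment_by_key.get(key_of(peptide))
        if assignment is None:
            raise TurnoverLabError(
                f"quantified peptide {peptide!r} is absent from every "
                "digest of the genotype alleles [stage: classify]"
            )
        if assignment.category == "ambiguous":
            exclusions.append(
                {"series": label, "stage": "classify", "time_h": "",
                 "reason": "ambiguous"}
            )
            continue
        try:
            result = _quantify_series(rows, mcols, params, label)
        except UnquantifiablePeptideError:
            exclusions.append(
                {"series": label, "stage": "mida", "time_h": "",
                 "reason": "unquantifiable"}
            )
            continue
        points, fit, total_abundance = result
        mida_rows.append(
            {
                "series": label,
                "peptide": peptide,
                "charge": int(charge),
                "n_sites": fit.n_sites,
                "enrichment_p": fit.enrichment_p,
                "plateau_rmsd": fit.rmsd,
                "total_abundance": total_abundance,
            }
        )
        retained, rejected = _mida.qc_filter(
            points, params.qc,
            total_ion_abundance=total_abundance,
            plateau_rmsd=fit.rmsd,
            plateau_margin=fit.runnerup_margin,
        )
        for rej in rejected:
            exclusions.append(
                {"series": label, "stage": "qc",
                 "time_h": rej.point.time_h, "reason": rej.reason}
            )
        if len(retained) < 3:
            exclusions.append(
                {"series": label, "stage": "kinetics", "time_h": "",
                 "reason": "too_few_points"}
            )
            continue
        series = _kin.FractionalSynthesisSeries(
            label=label,
            times_h=tuple(p.time_h for p in retained),
            f=tuple(p.f for p in retained),
            sd=tuple(p.sd for p in retained),
        )
        peptide_series.append((assignment, series))

    if not peptide_series:
        raise TurnoverLabError(
            "no peptide passed classification and QC [stage: kinetics]"
        )

    growth = _kin.fit_exponential_growth(
        list(zip(counts["time_h"], counts["cells_per_ml"]))
    )

    peptide_fit_rows: list[dict] = []
    fits_by_series: dict[str, _kin.KineticFitResult] = {}
    for assignment, series in peptide_series:
        fit = _kin.fit_single_exponential(series, params.weighting)
        fits_by_series[series.label] = fit
        peptide_fit_rows.append(
            _fit_row(fit, level="peptide", locus=assignment.locus,
                     group=_group_label(assignment))
        )

    group_fit_rows: list[dict] = []
    comparison_rows: list[dict] = []
    turnover_rows: list[dict] = []
    for locus in sorted({a.locus for a, _ in peptide_series}):
        locus_pairs = [(a, s) for a, s in peptide_series if a.locus == locus]
        series_list = [s for _, s in locus_pairs]
        if len(series_list) >= 2:
            cmp = _kin.compare_rates_f_test(series_list, params.weighting)
            pooled = cmp.shared_fit
            pooled_primary = cmp.p > params.alpha
            comparison_rows.append(
                {
                    "locus": locus,
                    "n_series": len(series_list),
                    "series": ";".join(s.label for s in series_list),
                    "F": cmp.F,
                    "df_num": cmp.df_num,
                    "df_den": cmp.df_den,
                    "p": cmp.p,
                    "pooled_primary": pooled_primary,
                }
            )
        else:
            pooled = fits_by_series[series_list[0].label]
            pooled_primary = True
        pooled = _relabel(pooled, f"HLA-{locus}")
        group_fit_rows.append(
            _fit_row(pooled, level="isotype", locus=locus, group=f"HLA-{locus}")
        )

        # allele-level pooled fits from allele-specific peptides
        alleles = sorted(
            {a.carriers[0] for a, _ in locus_pairs if a.category == "allele_specific"}
        )
        for allele in alleles:
            allele_series = [
                s for a, s in locus_pairs
                if a.category == "allele_specific" and a.carriers[0] == allele
            ]
            fit = (
                fits_by_series[allele_series[0].label]
                if len(allele_series) == 1
                else _kin.fit_single_exponential(
                    _kin.FractionalSynthesisSeries.concat(allele_series),
                    params.weighting,
                )
            )
            group_fit_rows.append(
                _fit_row(_relabel(fit, allele), level="allele",
                         locus=locus, group=allele)
            )

        est = _kin.correct_for_growth(pooled, growth)
        turnover_rows.append(
            {
                "isotype": f"HLA-{locus}",
                "k_obs": est.k_obs,
                "k_cell": est.k_cell,
                "k_to": est.k_to,
                "sem_k_to": est.sem_k_to,
                "t_half_to_h": est.t_half_to_h,
                "pooled_primary": pooled_primary,
                "flags": ";".join(sorted(est.flags)),
            }
        )

    return TurnoverReport(
        peptide_fits=_frame(peptide_fit_rows),
        group_fits=_frame(group_fit_rows),
        comparisons=_frame(
            comparison_rows,
            columns=["locus", "n_series", "series", "F", "df_num", "df_den",
                     "p", "pooled_primary"],
        ),
        turnover=_frame(turnover_rows),
        mida_fits=_frame(mida_rows),
        exclusions=_frame(
            exclusions, columns=["series", "stage", "time_h", "reason"]
        ),
        growth=growth,
        params=params,
    )


def _quantify_series(
    rows: pd.DataFrame,
    mcols: list[str],
    params: PipelineParams,
    label: str,
) -> tuple[list[_mida.FractionalSynthesisPoint], _mida.MIDAFit, float]:
    """MIDA stage for one (peptide, charge) series."""
    peptide = rows["peptide"].iloc[0]
    comp = _mida.composition_of(peptide)
    raw = rows[mcols].to_numpy(dtype=float)
    times = rows["time_h"].to_numpy(dtype=float)
    # trailing all-zero channels are table padding (mixed peptide sizes in
    # one quant file), not measurements: trim them before normalizing
    nonzero = np.nonzero(raw.sum(axis=0) > 0)[0]
    if nonzero.size == 0:
        raise UnquantifiablePeptideError(f"{label}: all channels are zero")
    raw = raw[:, : max(int(nonzero[-1]) + 1, 2)]
    fractions = raw / raw.sum(axis=1, keepdims=True)
    k_max = raw.shape[1] - 1
    total_abundance = float(raw.sum(axis=1).mean())

    n_range = (params.n_range[0], min(params.n_range[1], comp.H))
    if params.plateau_mode == "mixture":
        observations = [
            _mida.MassIsotopomerDistribution.from_raw(fractions[i])
            for i in range(len(times))
        ]
        fit, _lam = _mida.fit_plateau_mixture(
            observations, comp, params.enrichment_p, n_range
        )
    else:
        t_last = times.max()
        last_dist = _mida.MassIsotopomerDistribution.from_raw(
            fractions[times == t_last].mean(axis=0)
        )
        fit = _mida.fit_incorporation_sites(
            last_dist, comp, params.enrichment_p, n_range
        )

    if params.baseline_mode == "measured":
        t0 = times.min()
        baseline = _mida.MassIsotopomerDistribution.from_raw(
            fractions[times == t0].mean(axis=0)
        )
    else:
        baseline = _mida.natural_distribution(comp, k_max=k_max)

    points = []
    for i in range(len(times)):
        obs = _mida.MassIsotopomerDistribution.from_raw(fractions[i])
        points.append(
            _mida.fractional_synthesis(
                obs, baseline, fit.plateau_model,
                min_shift=params.min_shift, time_h=float(times[i]),
            )
        )
    return points, fit, total_abundance


def _group_label(a: _al.SpecificityAssignment) -> str:
    if a.category == "allele_specific":
        return a.carriers[0]
    return f"HLA-{a.locus}"


def _relabel(fit: _kin.KineticFitResult, label: str) -> _kin.KineticFitResult:
    from dataclasses import replace

    return replace(fit, label=label)


def _fit_row(
    fit: _kin.KineticFitResult, level: str, locus: str, group: str
) -> dict:
    return {
        "level": level,
        "label": fit.label,
        "locus": locus,
        "group": group,
        "n_points": fit.n_points,
        "k_obs": fit.k_obs,
        "sem": fit.sem,
        "ci95_lo": fit.ci95[0],
        "ci95_hi": fit.ci95[1],
        "rss": fit.rss,
        "df": fit.df,
        "t_half_h": fit.t_half_h,
        "flags": ";".join(sorted(fit.flags)),
    }


def _frame(rows: list[dict], columns: list[str] | None = None) -> pd.DataFrame:
    if rows:
        return pd.DataFrame(rows)
    return pd.DataFrame(columns=columns or [])


def write_report(report: TurnoverReport, out_dir: str | Path) -> dict[str, Path]:
    """Write report tables and a markdown summary; deterministic on rerun."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "fits.csv": pd.concat(
            [report.peptide_fits, report.group_fits], ignore_index=True
        ),
        "comparisons.csv": report.comparisons,
        "turnover.csv": report.turnover,
        "mida_fits.csv": report.mida_fits,
        "exclusions.csv": report.exclusions,
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths[name] = path
    summary = _summary_markdown(report)
    (out / "summary.md").write_text(summary)
    paths["summary.md"] = out / "summary.md"
    (out / "run.log").write_text(_run_log(report))
    paths["run.log"] = out / "run.log"
    return paths


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isinf(x):
        return "inf"
    return f"{x:.4g}"


def _summary_markdown(report: TurnoverReport) -> str:
    buf = io.StringIO()
    buf.write("# Turnover analysis summary\n\n")
    g = report.growth
    buf.write(
        f"Cell growth: k_cell = {_fmt(g.k_cell)}/h "
        f"(doubling time {_fmt(g.t_double_h)} h)"
    )
    if g.flags:
        buf.write(f" [{';'.join(sorted(g.flags))}]")
    buf.write("\n\n## Pooled isotype fits\n\n")
    iso = report.group_fits[report.group_fits["level"] == "isotype"]
    for _, row in iso.iterrows():
        buf.write(
            f"- {row['label']}: k_obs = {_fmt(row['k_obs'])} ± "
            f"{_fmt(row['sem'])}/h "
            f"(95% CI {_fmt(row['ci95_lo'])}–{_fmt(row['ci95_hi'])}), "
            f"t_half = {_fmt(row['t_half_h'])} h, "
            f"n = {int(row['n_points'])} points\n"
        )
    buf.write("\n## Rate-equality F tests (per locus)\n\n")
    if len(report.comparisons) == 0:
        buf.write("(no locus had two or more peptide series)\n")
    for _, row in report.comparisons.iterrows():
        verdict = "pooled" if row["pooled_primary"] else "separate"
        buf.write(
            f"- HLA-{row['locus']}: F({int(row['df_num'])}, "
            f"{int(row['df_den'])}) = {_fmt(row['F'])}, p = {_fmt(row['p'])} "
            f"→ {verdict} fit primary\n"
        )
    buf.write("\n## Growth-corrected turnover\n\n")
    for _, row in report.turnover.iterrows():
        buf.write(
            f"- {row['isotype']}: k_TO = {_fmt(row['k_to'])} ± "
            f"{_fmt(row['sem_k_to'])}/h, t_half(TO) = "
            f"{_fmt(row['t_half_to_h'])} h"
        )
        if row["flags"]:
            buf.write(f" [{row['flags']}]")
        buf.write("\n")
    n_excluded = len(set(report.exclusions["series"])) if len(report.exclusions) else 0
    buf.write(
        f"\n{len(report.peptide_fits)} peptide series fitted; "
        f"{n_excluded} series with exclusions (see exclusions.csv).\n"
    )
    return buf.getvalue()


def _run_log(report: TurnoverReport) -> str:
    lines = ["# pipeline parameters (all defaults logged for provenance)"]
    params = asdict(report.params)
    for key in sorted(params):
        lines.append(f"{key} = {params[key]!r}")
    return "\n".join(lines) + "\n"
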