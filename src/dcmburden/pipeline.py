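"""End-to-end orchestration and human-readable reporting.

``run_all`` drives filter -> burden -> (optional) penetrance from a
single YAML configuration and writes the qualifying-variant table, a
machine-readable burden report, the formatted summary table and a run
manifest (thresholds, seed, input checksums, package version) so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .burden import BurdenResult, run_burden
from .filtering import FilterConfig, qualification_report
from .io import (
    load_cohort,
    read_config,
    sha256_of,
    write_burden_report,
    write_json,
    write_qualifying_table,
)
from .penetrance import DEFAULT_DRAWS, DEFAULT_SEED, sex_stratified_penetrance

log = logging.getLogger("dcmburden")

__all__ = ["run_all", "format_table1", "round_half_up"]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding at a fixed number of decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_or(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    if x == float("inf"):
        return "Inf"
    return f"{round_half_up(x, 2):.2f}"


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "NA"
    return f"{float(f'{p:.2g}'):g}"


def format_table1(results: Sequence[BurdenResult]) -> str:
    """Render burden results as a text table mirroring the cohort summary.

    Columns: gene, carrier count and percentage per sex, conditional-MLE
    OR with its 95% CI (2 decimals, half-up; an infinite bound renders
    as an open interval), and the FDR-adjusted p to 2 significant
    figures.  Excluded genes are listed beneath with their reasons.
    """
    if not results:
        raise ValueError("no burden results to format")
    tested = [r for r in results if r.tested]
    excluded = [r for r in results if not r.tested]
    lines = ["Gene\tN(F)\t%(F)\tN(M)\t%(M)\tOR [95% CI]\tP (FDR-adjusted)"]
    for r in tested:
        t = r.table
        lo, hi = r.ci95
        ci = f"{_fmt_or(r.or_cmle)} [{_fmt_or(lo)} - {_fmt_or(hi)}" + (")" if hi == float("inf") else "]")
        lines.append(
            f"{r.gene}\t{t.a}\t{100 * t.a / t.n_female:.2f}\t"
            f"{t.c}\t{100 * t.c / t.n_male:.2f}\t{ci}\t{_fmt_p(r.p_fdr)}"
        )
    if excluded:
        lines.append("")
        lines.append("Excluded genes:")
        for r in excluded:
            lines.append(f"{r.gene}\t{r.exclusion_reason}")
    return "\n".join(lines) + "\n"


@dataclass
class RunOutputs:
    qualifying_table: Path
    burden_report: Path
    summary_table: Path
    manifest: Path
    penetrance_report: Optional[Path] = None
    results: Optional[list] = None


def run_all(config_path, out_dir=None, seed: Optional[int] = None,
            verbose: bool = False) -> RunOutputs:
    """Run the full pipeline from a YAML configuration.

    Produces ``qualifying_variants.tsv``, ``burden_report.tsv``,
    ``burden_table.txt``, optionally ``penetrance.tsv`` and always a
    ``run_manifest.json`` recording thresholds, seed and input
    checksums.  Stage errors propagate with the stage name attached.
    """
    cfg = read_config(config_path)
    out = Path(out_dir or cfg.get("out_dir") or ".")
    out.mkdir(parents=True, exist_ok=True)
    inputs = cfg["inputs"]
    fcfg: FilterConfig = cfg["filter"]
    rules: list = cfg["rules"]
    seed = seed if seed is not None else (cfg.get("seed") or DEFAULT_SEED)

    try:
        cohort = load_cohort(inputs["vcf"], inputs["annotations"], inputs["samples"])
    except Exception as e:
        raise RuntimeError(f"stage 'load': {e}") from e

    try:
        report = qualification_report(cohort.variants, rules, fcfg)
        qual_path = out / "qualifying_variants.tsv"
        write_qualifying_table(qual_path, report, verbose=verbose)
    except Exception as e:
        raise RuntimeError(f"stage 'filter': {e}") from e

    burden_opts = cfg.get("burden", {})
    subset_ancestry = burden_opts.get("subset_ancestry")
    subset = (lambda s: s.ancestry == subset_ancestry) if subset_ancestry else None
    try:
        results = run_burden(
            cohort,
            rules,
            fcfg,
            subset_filter=subset,
            min_carriers=int(burden_opts.get("min_carriers", 5)),
            alternative=burden_opts.get("alternative", "two-sided"),
        )
    except Exception as e:
        raise RuntimeError(f"stage 'burden': {e}") from e
    if all(not r.tested for r in results):
        log.warning("no gene reached the minimum carrier count; all excluded")
    report_path = out / "burden_report.tsv"
    write_burden_report(report_path, results)
    table_path = out / "burden_table.txt"
    table_path.write_text(format_table1(results))

    pen_path = None
    pen_cfg = cfg.get("penetrance", {})
    if pen_cfg.get("case_counts") and pen_cfg.get("pop_counts"):
        try:
            pen_path = out / "penetrance.tsv"
            _penetrance_stage(pen_cfg, pen_path, seed)
        except Exception as e:
            raise RuntimeError(f"stage 'penetrance': {e}") from e

    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "filter": vars(fcfg) if not hasattr(fcfg, "__dataclass_fields__") else {
            k: getattr(fcfg, k) for k in fcfg.__dataclass_fields__
        },
        "rules": [
            {"gene": r.gene, "class": r.qualifying_class.value,
             "constitutive_exon": r.requires_constitutive_exon}
            for r in rules
        ],
        "burden": dict(burden_opts),
        "inputs": {k: {"path": str(v), "sha256": sha256_of(v)} for k, v in inputs.items()},
    }
    manifest_path = out / "run_manifest.json"
    write_json(manifest_path, manifest)
    return RunOutputs(
        qualifying_table=qual_path,
        burden_report=report_path,
        summary_table=table_path,
        manifest=manifest_path,
        penetrance_report=pen_path,
        results=results,
    )


def _penetrance_stage(pen_cfg: dict, out_path: Path, seed: int) -> None:
    import pandas as pd

    cases = pd.read_csv(pen_cfg["case_counts"], sep="\t")
    pops = pd.read_csv(pen_cfg["pop_counts"], sep="\t")
    prev = pen_cfg.get("prevalence")
    if prev is None:
        from .penetrance import DEFAULT_PREVALENCE

        log.warning(
            "no prevalence configured; using the shipped default %.4g — "
            "set it explicitly for any real analysis", DEFAULT_PREVALENCE,
        )
        prev = DEFAULT_PREVALENCE
    if not isinstance(prev, dict):
        prev = {"all": float(prev), "female": float(prev), "male": float(prev)}
    n_draws = int(pen_cfg.get("draws", DEFAULT_DRAWS))
    rows = []
    for gene in sorted(set(cases["gene"]) & set(pops["gene"])):
        case_counts = {
            r.stratum: (int(r.carriers), int(r.n))
            for r in cases[cases["gene"] == gene].itertuples()
        }
        pop_counts = {
            r.stratum: (int(r.carriers), int(r.n))
            for r in pops[pops["gene"] == gene].itertuples()
        }
        for est in sex_stratified_penetrance(
            gene, case_counts, pop_counts, prev,
            n_draws=n_draws, seed=int(pen_cfg.get("seed", seed)),
        ):
            rows.append(
                {
                    "gene": est.gene,
                    "stratum": est.stratum,
                    "penetrance": est.point,
                    "ci_lower": est.ci95[0],
                    "ci_upper": est.ci95[1],
                    "prevalence": est.prevalence_used,
                    "n_draws": est.n_draws,
                    "n_clamped": est.n_clamped,
                }
            )
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False, float_format="%.6g")
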