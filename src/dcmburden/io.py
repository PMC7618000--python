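"""Reading and writing the pipeline's file formats.

Genotypes come from a multi-sample VCF (v4.x, read with cyvcf2);
multi-allelic sites are split into bi-allelic records with per-sample
alternate-allele counts recomputed per split allele.  Variant
annotations (gene, consequence terms, per-population allele frequencies,
TTN exon inclusion, QC metrics) live in a tab-separated side table keyed
by ``chrom:pos:ref:alt``.  The sample sheet and all reports are TSV;
run configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import ConsequenceClass, FilterConfig, GeneRule, VariantRecord
from .burden import SampleRecord

log = logging.getLogger("dcmburden")

__all__ = [
    "Genotypes",
    "Cohort",
    "read_vcf",
    "read_annotations",
    "read_samples",
    "load_cohort",
    "read_config",
    "write_vcf",
    "write_samples",
    "write_annotations",
    "write_qualifying_table",
    "write_burden_report",
    "sha256_of",
]


class Genotypes:
    """Alternate-allele counts per variant (rows) and sample (columns).

    The matrix is int8 with ``-1`` marking missing genotypes.
    """

    def __init__(self, sample_ids: Sequence[str], keys: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.shape != (len(keys), len(sample_ids)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(keys)} variants x {len(sample_ids)} samples"
            )
        self.sample_ids = list(sample_ids)
        self.keys = list(keys)
        self.matrix = matrix
        self._row = {k: i for i, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.keys)

    def alt_counts(self, key: str) -> np.ndarray:
        return self.matrix[self._row[key]]

    def any_alt(self, keys) -> np.ndarray:
        """Boolean per sample: carries >= 1 alt allele at >= 1 of ``keys``."""
        rows = [self._row[k] for k in keys if k in self._row]
        if not rows:
            return np.zeros(len(self.sample_ids), dtype=bool)
        return (self.matrix[rows] > 0).any(axis=0)

    def genotype_counts(self, key: str) -> tuple:
        """(n_homref, n_het, n_homalt) over non-missing genotypes."""
        row = self.alt_counts(key)
        return (
            int((row == 0).sum()),
            int((row == 1).sum()),
            int((row >= 2).sum()),
        )


@dataclass
class Cohort:
    """Samples, their genotypes and the annotated candidate variants."""

    samples: list
    genotypes: Genotypes
    variants: list = field(default_factory=list)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample sheet")
        missing = set(ids) - set(self.genotypes.sample_ids)
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_vcf(path) -> Genotypes:
    """Read a multi-sample VCF into per-sample alternate-allele counts.

    Multi-allelic sites are split into one bi-allelic record per ALT
    allele; each split record counts only its own allele, so a sample
    het for two different ALTs contributes one allele to each record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    keys, rows = [], []
    for variant in vcf:
        alts = variant.ALT
        gts = variant.genotypes  # [allele0, allele1, phased] per sample
        for alt_idx, alt in enumerate(alts, start=1):
            counts = np.zeros(len(sample_ids), dtype=np.int8)
            for j, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(al < 0 for al in alleles):
                    counts[j] = -1
                else:
                    counts[j] = sum(1 for al in alleles if al == alt_idx)
            keys.append(f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}")
            rows.append(counts)
    vcf.close()
    matrix = np.vstack(rows) if rows else np.zeros((0, len(sample_ids)), dtype=np.int8)
    log.info("read %d bi-allelic variant records for %d samples", len(keys), len(sample_ids))
    return Genotypes(sample_ids, keys, matrix)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "."):
        return None
    return float(value)


def read_annotations(path, genotypes: Optional[Genotypes] = None) -> list:
    """Read the per-variant annotation table into :class:`VariantRecord`.

    Expected header columns: ``chrom pos ref alt gene consequence_terms``
    (comma-joined), any number of ``af_<population>`` columns, and
    optional ``ttn_psi call_rate qual_by_depth``.  When ``genotypes`` is
    given, cohort genotype counts are recomputed from the matrix for the
    Hardy-Weinberg test; otherwise optional ``gt_homref gt_het gt_homalt``
    columns are used.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    af_cols = [c for c in df.columns if c.startswith("af_")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pop_afs = {}
        for c in af_cols:
            af = _opt_float(d[c])
            if af is not None:
                pop_afs[c[3:]] = af
        key = f"{d['chrom']}:{int(d['pos'])}:{d['ref']}:{d['alt']}"
        if genotypes is not None and key in genotypes._row:
            gt_counts: Optional[tuple] = genotypes.genotype_counts(key)
        elif {"gt_homref", "gt_het", "gt_homalt"} <= set(df.columns):
            vals = (_opt_float(d["gt_homref"]), _opt_float(d["gt_het"]), _opt_float(d["gt_homalt"]))
            gt_counts = None if any(v is None for v in vals) else tuple(int(v) for v in vals)
        else:
            gt_counts = None
        records.append(
            VariantRecord(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                gene=str(d["gene"]),
                consequence_terms=frozenset(str(d["consequence_terms"]).split(",")),
                pop_afs=pop_afs,
                ttn_psi=_opt_float(d.get("ttn_psi")),
                call_rate=_opt_float(d.get("call_rate")),
                qual_by_depth=_opt_float(d.get("qual_by_depth")),
                genotype_counts=gt_counts,
            )
        )
    return records


def read_samples(path) -> list:
    """Read the sample sheet (columns: sample_id, sex, ancestry, status)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SampleRecord(
            sample_id=row.sample_id,
            sex=row.sex,
            ancestry=getattr(row, "ancestry", "European"),
            status=getattr(row, "status", "case"),
        )
        for row in df.itertuples(index=False)
    ]


def load_cohort(vcf_path, annotation_path, sample_path) -> Cohort:
    """Load genotypes, annotations and the sample sheet into one cohort."""
    genotypes = read_vcf(vcf_path)
    variants = read_annotations(annotation_path, genotypes=genotypes)
    samples = read_samples(sample_path)
    return Cohort(samples=samples, genotypes=genotypes, variants=variants)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CLASS_ALIASES = {
    "plof": ConsequenceClass.PLOF,
    "lof": ConsequenceClass.PLOF,
    "missense": ConsequenceClass.MISSENSE,
    "ms": ConsequenceClass.MISSENSE,
    "pav": ConsequenceClass.PAV,
}


def parse_gene_rules(entries) -> list:
    rules = []
    for e in entries:
        cls = _CLASS_ALIASES.get(str(e["class"]).lower())
        if cls is None:
            raise ValueError(f"unknown qualifying class {e['class']!r} for {e['gene']}")
        rules.append(
            GeneRule(
                gene=str(e["gene"]),
                qualifying_class=cls,
                requires_constitutive_exon=bool(e.get("constitutive_exon", False)),
            )
        )
    return rules


def read_config(path) -> dict:
    """Parse the YAML run configuration.

    Returns a dict with keys ``filter`` (:class:`FilterConfig`), ``rules``
    (list of :class:`GeneRule`), plus the raw ``inputs``, ``burden``,
    ``penetrance``, ``seed`` and ``out_dir`` sections.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = FilterConfig(**(raw.get("filter") or {}))
    rules = parse_gene_rules(raw["genes"]) if raw.get("genes") else list(
        __import__("dcmburden.filtering", fromlist=["DEFAULT_GENE_RULES"]).DEFAULT_GENE_RULES
    )
    return {
        "filter": cfg,
        "rules": rules,
        "inputs": raw.get("inputs", {}),
        "burden": raw.get("burden", {}),
        "penetrance": raw.get("penetrance", {}),
        "seed": raw.get("seed"),
        "out_dir": raw.get("out_dir"),
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_vcf(path, genotypes: Genotypes, variant_meta: Optional[dict] = None):
    """Write genotypes as an uncompressed VCFv4.2 with GT-only FORMAT."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({k.split(":")[0] for k in genotypes.keys}, key=_chrom_order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        order = sorted(
            range(len(genotypes.keys)),
            key=lambda i: (_chrom_order(genotypes.keys[i].split(":")[0]),
                           int(genotypes.keys[i].split(":")[1])),
        )
        for i in order:
            chrom, pos, ref, alt = genotypes.keys[i].split(":")
            row = genotypes.matrix[i]
            cells = "\t".join(gt_str[int(min(g, 2))] for g in row)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{cells}\n")
    log.info("wrote %d variants for %d samples to %s", len(genotypes), len(genotypes.sample_ids), path)


def _chrom_order(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_samples(path, samples: Sequence[SampleRecord]):
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "sex": [s.sex for s in samples],
            "ancestry": [s.ancestry for s in samples],
            "status": [s.status for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def write_annotations(path, variants: Sequence[VariantRecord]):
    pops = sorted({p for v in variants for p in v.pop_afs})
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence_terms": ",".join(sorted(v.consequence_terms)),
        }
        for p in pops:
            row[f"af_{p}"] = v.pop_afs.get(p, 0.0)
        row["ttn_psi"] = "NA" if v.ttn_psi is None else v.ttn_psi
        row["call_rate"] = "NA" if v.call_rate is None else v.call_rate
        row["qual_by_depth"] = "NA" if v.qual_by_depth is None else v.qual_by_depth
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_qualifying_table(path, report: dict, verbose: bool = False):
    """Write per-variant qualification verdicts (key, gene, reason)."""
    rows = [
        {"variant": key, "gene": gene, "verdict": reason}
        for key, (gene, reason) in report.items()
        if verbose or reason == "qualifies"
    ]
    pd.DataFrame(rows, columns=["variant", "gene", "verdict"]).to_csv(path, sep="\t", index=False)


def write_burden_report(path, results) -> None:
    """Machine-readable burden report (one row per gene)."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "gene": r.gene,
                "n_female_carriers": t.a,
                "pct_female": 100.0 * t.a / t.n_female if t.n_female else float("nan"),
                "n_male_carriers": t.c,
                "pct_male": 100.0 * t.c / t.n_male if t.n_male else float("nan"),
                "or_cmle": r.or_cmle,
                "or_sample": r.or_sample,
                "ci_lower": r.ci95[0] if r.ci95 else None,
                "ci_upper": r.ci95[1] if r.ci95 else None,
                "p": r.p,
                "p_fdr": r.p_fdr,
                "tested": r.tested,
                "exclusion_reason": r.exclusion_reason or "",
                "n_qualifying_variants": r.n_qualifying_variants,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
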