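"""Readers and writers for the formats the pipeline touches.

VCF input goes through :mod:`pysam`; the tabular inputs (clinical table,
variant annotation table, gene registry) are plain TSV read with pandas.
Multi-allelic VCF records are decomposed so every observation carries exactly
one alt allele, with shared prefix/suffix trimming (left alignment) applied
to decomposed indels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .model import (
    AnnotationBundle,
    ArrhythmiaCategory,
    ClinicalRecord,
    Consequence,
    FREQUENCY_SOURCES,
    GeneRegistry,
    GenotypeCall,
    PREDICTOR_TOOLS,
    Sex,
    VariantObservation,
    Zygosity,
)

#: tokens accepted as missing values in annotation tables (ANNOVAR-style dialects)
NA_TOKENS = frozenset({"NA", "nan", "NaN", ".", ""})


class SchemaError(ValueError):
    """A file violates the expected schema."""


def _trim_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a decomposed allele pair by trimming shared suffix then prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _zygosity_for_alt(gt: tuple, alt_index: int) -> Zygosity:
    """Zygosity of one sample w.r.t. alt allele number ``alt_index`` (1-based).

    Hemizygous single-allele genotypes carrying the alt are mapped to hom_alt
    (allele-balance QC applies to hets only).
    """
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Zygosity.missing
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 0:
        return Zygosity.hom_ref
    if n_alt == len(alleles):
        return Zygosity.hom_alt
    return Zygosity.het


def read_vcf(path, sample_whitelist: Optional[Iterable[str]] = None) -> list[VariantObservation]:
    """Read a VCF into per-(patient, alt) observations, without annotations.

    One observation is emitted per decomposed alt allele per sample whose
    genotype carries that allele. Records failing FILTER are *kept* with
    their filter status preserved; dropping them is a filtering-stage rule.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise SchemaError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise SchemaError(f"{path}: mandatory FORMAT key GT not declared in header")
        whitelist = set(sample_whitelist) if sample_whitelist is not None else None
        observations: list[VariantObservation] = []
        for rec in vf:
            filter_keys = list(rec.filter.keys())
            filter_status = ";".join(filter_keys) if filter_keys else "PASS"
            alts = rec.alts or ()
            for sample_name, sample in rec.samples.items():
                if whitelist is not None and sample_name not in whitelist:
                    continue
                gt = sample.get("GT")
                if gt is None:
                    continue
                ad = sample.get("AD")
                for alt_index, alt in enumerate(alts, start=1):
                    if alt is None or alt == "*":
                        continue
                    zyg = _zygosity_for_alt(gt, alt_index)
                    if zyg in (Zygosity.hom_ref, Zygosity.missing):
                        continue
                    ad_pair = None
                    if ad is not None and len(ad) > alt_index and ad[0] is not None and ad[alt_index] is not None:
                        ad_pair = (int(ad[0]), int(ad[alt_index]))
                    pos, ref, alt_trim = _trim_allele_pair(rec.pos, rec.ref, alt)
                    call = GenotypeCall(
                        patient_id=sample_name,
                        gt=zyg,
                        dp=None if sample.get("DP") is None else int(sample.get("DP")),
                        gq=None if sample.get("GQ") is None else int(sample.get("GQ")),
                        ad=ad_pair,
                        filter_status=filter_status,
                    )
                    observations.append(
                        VariantObservation(rec.chrom, pos, ref, alt_trim, sample_name, call)
                    )
    return observations


_CLINICAL_COLUMNS = ("patient_id", "sex", "onset_age", "category", "cardiomyopathy")

_SEX_LABELS = {"female": Sex.female, "f": Sex.female, "male": Sex.male, "m": Sex.male}
_BOOL_LABELS = {"true": True, "1": True, "yes": True, "y": True,
                "false": False, "0": False, "no": False, "n": False}


def _parse_category(label: str) -> ArrhythmiaCategory:
    low = label.strip().lower()
    for cat in ArrhythmiaCategory:
        if low.startswith(cat.value):
            return cat
    raise SchemaError(f"unknown arrhythmia category {label!r}")


def read_clinical(path) -> list[ClinicalRecord]:
    """Read the tab-separated clinical table (one row per patient)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing clinical columns {missing}")
    records = []
    seen = set()
    for i, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        if pid in seen:
            raise SchemaError(f"{path}: duplicate patient_id {pid!r}")
        seen.add(pid)
        sex_label = str(row["sex"]).strip().lower()
        if sex_label not in _SEX_LABELS:
            raise SchemaError(f"{path}: unknown sex {row['sex']!r} (row {i + 1})")
        try:
            age = int(str(row["onset_age"]).strip())
        except ValueError as exc:
            raise SchemaError(f"{path}: unparseable onset_age {row['onset_age']!r} (row {i + 1})") from exc
        cm_label = str(row["cardiomyopathy"]).strip().lower()
        if cm_label not in _BOOL_LABELS:
            raise SchemaError(f"{path}: unparseable cardiomyopathy {row['cardiomyopathy']!r} (row {i + 1})")
        records.append(
            ClinicalRecord(
                patient_id=pid,
                sex=_SEX_LABELS[sex_label],
                onset_age=age,
                category=_parse_category(str(row["category"])),
                cardiomyopathy=_BOOL_LABELS[cm_label],
            )
        )
    return records


_ANNOTATION_KEY = ("chrom", "pos", "ref", "alt")
_FREQ_COLUMNS = {src: f"freq_{src}" for src in FREQUENCY_SOURCES}


def _parse_na(token) -> Optional[str]:
    s = "" if token is None or (isinstance(token, float) and pd.isna(token)) else str(token).strip()
    return None if s in NA_TOKENS else s


def read_annotation_table(path) -> dict:
    """Read the variant annotation TSV into a (chrom, pos, ref, alt) -> AnnotationBundle map.

    Missing-value tokens (``NA``, ``nan``, ``.``, empty) become None; they are
    *not* zeroed here — the frequency-zeroing rule belongs to the filter stage.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = list(_ANNOTATION_KEY) + ["gene", "consequence"] + list(_FREQ_COLUMNS.values()) + list(PREDICTOR_TOOLS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing annotation columns {missing}")
    table = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # data rows start at line 2
        row = row._asdict()
        try:
            consequence = Consequence(row["consequence"].strip())
        except ValueError as exc:
            raise SchemaError(f"{path} row {i}: unknown consequence {row['consequence']!r}") from exc
        freqs = {}
        for src, col in _FREQ_COLUMNS.items():
            tok = _parse_na(row[col])
            if tok is None:
                freqs[src] = None
            else:
                val = float(tok)
                if not (0.0 <= val <= 1.0):
                    raise SchemaError(f"{path} row {i}: frequency {col}={val} outside [0, 1]")
                freqs[src] = val
        predictors = {}
        for tool in PREDICTOR_TOOLS:
            tok = _parse_na(row[tool])
            if tok is None:
                predictors[tool] = None
            elif tool == "mutation_taster":
                predictors[tool] = tok
            else:
                predictors[tool] = float(tok)
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        table[key] = AnnotationBundle(
            gene=row["gene"],
            consequence=consequence,
            hgvs_p=_parse_na(row.get("hgvs_p", "")),
            freqs=freqs,
            predictors=predictors,
        )
    return table


def read_registry(genes_path, chromosomes_path=None) -> GeneRegistry:
    """Read the gene registry (gene, chrom, protein_length) and, optionally, a
    chromosome table (chrom, protein_coding_gene_count). Without the latter,
    per-chromosome gene counts are derived by counting registry genes."""
    genes_df = pd.read_csv(genes_path, sep="\t")
    genes_df.columns = [c.strip().lower() for c in genes_df.columns]
    genes = {
        str(r.gene): (str(r.chrom), int(r.protein_length))
        for r in genes_df.itertuples(index=False)
    }
    if chromosomes_path is not None:
        chrom_df = pd.read_csv(chromosomes_path, sep="\t")
        chrom_df.columns = [c.strip().lower() for c in chrom_df.columns]
        counts = {
            str(r.chrom): int(r.protein_coding_gene_count)
            for r in chrom_df.itertuples(index=False)
        }
    else:
        counts = genes_df.groupby("chrom")["gene"].count().astype(int).to_dict()
    return GeneRegistry(genes=genes, chromosome_gene_counts=counts)


# ---------------------------------------------------------------------------
# retained-observation frame: the handoff format between pipeline stages

RETAINED_COLUMNS = [
    "chrom", "pos", "ref", "alt", "patient_id", "gene", "consequence",
    "hgvs_p", "benign_votes", "deleterious_votes", "missing_votes",
]


def retained_to_frame(retained: list[VariantObservation]) -> pd.DataFrame:
    """Flatten retained observations (with annotations and predictor votes)
    into the tabular handoff format consumed by the downstream modules."""
    from .filtering import predictor_verdict

    rows = []
    for obs in retained:
        verdict = predictor_verdict(obs.ann.predictors)
        rows.append({
            "chrom": obs.chrom,
            "pos": obs.pos,
            "ref": obs.ref,
            "alt": obs.alt,
            "patient_id": obs.patient_id,
            "gene": obs.ann.gene,
            "consequence": obs.ann.consequence.value,
            "hgvs_p": obs.ann.hgvs_p if obs.ann.hgvs_p is not None else "",
            "benign_votes": verdict.benign_votes,
            "deleterious_votes": verdict.deleterious_votes,
            "missing_votes": verdict.missing_votes,
        })
    df = pd.DataFrame(rows, columns=RETAINED_COLUMNS)
    return df.sort_values(["chrom", "pos", "ref", "alt", "patient_id"], kind="stable").reset_index(drop=True)


def read_retained(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "hgvs_p": str}, keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    for col in ("benign_votes", "deleterious_votes", "missing_votes"):
        df[col] = df[col].astype(int)
    return df


def write_clinical(records: list[ClinicalRecord], path) -> None:
    rows = [{
        "patient_id": r.patient_id,
        "sex": r.sex.value,
        "onset_age": r.onset_age,
        "category": r.category.value,
        "cardiomyopathy": str(r.cardiomyopathy).lower(),
    } for r in records]
    pd.DataFrame(rows, columns=list(_CLINICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def _fmt(value) -> str:
    return "NA" if value is None else repr(value) if isinstance(value, float) else str(value)


def write_annotation_table(annotations: dict, path) -> None:
    """Write a (chrom, pos, ref, alt) -> AnnotationBundle map as TSV; missing
    values become ``NA`` tokens. Rows sorted by key for determinism."""
    rows = []
    for (chrom, pos, ref, alt) in sorted(annotations, key=lambda k: (k[0], k[1], k[2], k[3])):
        ann = annotations[(chrom, pos, ref, alt)]
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
               "gene": ann.gene, "consequence": ann.consequence.value,
               "hgvs_p": ann.hgvs_p if ann.hgvs_p is not None else "NA"}
        for src, col in _FREQ_COLUMNS.items():
            row[col] = _fmt(ann.freqs.get(src))
        for tool in PREDICTOR_TOOLS:
            row[tool] = _fmt(ann.predictors.get(tool))
        rows.append(row)
    columns = (list(_ANNOTATION_KEY) + ["gene", "consequence", "hgvs_p"]
               + list(_FREQ_COLUMNS.values()) + list(PREDICTOR_TOOLS))
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_registry(registry: GeneRegistry, genes_path, chromosomes_path) -> None:
    gene_rows = [{"gene": g, "chrom": c, "protein_length": plen}
                 for g, (c, plen) in sorted(registry.genes.items())]
    pd.DataFrame(gene_rows, columns=["gene", "chrom", "protein_length"]).to_csv(
        genes_path, sep="\t", index=False)
    chrom_rows = [{"chrom": c, "protein_coding_gene_count": n}
                  for c, n in sorted(registry.chromosome_gene_counts.items())]
    pd.DataFrame(chrom_rows, columns=["chrom", "protein_coding_gene_count"]).to_csv(
        chromosomes_path, sep="\t", index=False)


def write_results(tables: dict, out_dir, manifest: Optional[dict] = None) -> list[Path]:
    """Write each named DataFrame as ``<name>.tsv`` (deterministic column
    order, index dropped) plus a JSON run manifest; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in sorted(tables.items()):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    manifest_payload = {"tables": {name: len(df) for name, df in sorted(tables.items())}}
    if manifest:
        manifest_payload.update(manifest)
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest_payload, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
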