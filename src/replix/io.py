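"""Readers and writers for the pipeline's tab-separated interchange files.

All tables are UTF-8 TSV with a header row and "." for missing values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .catalog import CatalogEntry, CuratedAssociation, LDTable, PlatformManifest
from .phenotyping import IncidenceCurve, PhenotypeAssignment, PhenotypeDefinition, SurveyResponse

__all__ = [
    "read_catalog",
    "read_ld",
    "read_platform",
    "read_reference_freqs",
    "read_responses",
    "read_covariates",
    "read_phenotype_definitions",
    "read_dosages",
    "read_vcf_dosages",
    "write_curation_report",
    "write_assignments",
]

_NA = "."


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], dtype={"snp_id": str})


def _to_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("1", "true", "yes", "y")


def read_catalog(path) -> list[CatalogEntry]:
    """Parse a catalog TSV into validated entries.

    Malformed rows raise a ValueError naming the offending row index.
    """
    df = _read_tsv(path)
    entries = []
    for idx, row in df.iterrows():
        try:
            p = float(row["p_value"])
            effect = None if pd.isna(row["effect"]) else float(row["effect"])
            raf = None if pd.isna(row.get("raf")) else float(row["raf"])
            entries.append(
                CatalogEntry(
                    snp_id=str(row["snp_id"]),
                    phenotype=str(row["phenotype"]),
                    risk_allele=str(row["risk_allele"]),
                    other_allele=str(row["other_allele"]),
                    raf_controls=raf,
                    effect=effect,
                    trait_type=str(row["trait_type"]),
                    p_value=p,
                    ancestry=str(row["ancestry"]),
                    study_id=str(row["study_id"]),
                    n_cases=0 if pd.isna(row.get("n_cases")) else int(row["n_cases"]),
                    n_controls=0 if pd.isna(row.get("n_controls")) else int(row["n_controls"]),
                    single_snp=_to_bool(row.get("single_snp", True)),
                    includes_this_cohort=_to_bool(row.get("includes_cohort", False)),
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"catalog row {idx}: {exc}") from exc
    return entries


def read_ld(path) -> LDTable:
    df = _read_tsv(path)
    table = LDTable()
    for _, row in df.iterrows():
        table.set(str(row["snp_a"]), str(row["snp_b"]), float(row["r2"]))
    return table


def read_platform(path) -> PlatformManifest:
    df = _read_tsv(path)
    return PlatformManifest(call_rate={str(r["snp_id"]): float(r["call_rate"]) for _, r in df.iterrows()})


def read_reference_freqs(path) -> dict[str, float]:
    df = _read_tsv(path)
    return {str(r["snp_id"]): float(r["ref_freq"]) for _, r in df.iterrows() if not pd.isna(r["ref_freq"])}


def read_responses(path) -> list[SurveyResponse]:
    df = _read_tsv(path)
    out = []
    for _, r in df.iterrows():
        onset = None if pd.isna(r.get("onset_age")) else float(r["onset_age"])
        out.append(SurveyResponse(str(r["subject_id"]), str(r["question_id"]), str(r["answer"]), onset))
    return out


def read_covariates(path) -> pd.DataFrame:
    df = _read_tsv(path)
    return df.set_index("subject_id")


def read_phenotype_definitions(path) -> list[PhenotypeDefinition]:
    """Phenotype definitions from a YAML config.

    Schema per phenotype: ``questions`` (list), optional ``min_onset_age``,
    ``max_onset_age``, ``sex`` (male/female), ``smokers_only`` (bool), and
    ``incidence`` with ``ages``/``cum_incidence`` lists for the control age
    rule.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    defs = []
    for name, d in (cfg.get("phenotypes") or {}).items():
        curve = None
        if "incidence" in d:
            curve = IncidenceCurve(d["incidence"]["ages"], d["incidence"]["cum_incidence"])
        defs.append(
            PhenotypeDefinition(
                phenotype=name,
                question_ids=tuple(d["questions"]),
                min_onset_age=d.get("min_onset_age"),
                max_onset_age=d.get("max_onset_age"),
                sex_restriction=d.get("sex"),
                smoking_restriction=d.get("smokers_only"),
                control_age_rule=curve,
            )
        )
    return defs


def read_dosages(path) -> pd.DataFrame:
    """Long dosage TSV (snp_id, subject_id, dosage) -> subjects x SNPs
    frame with NaN for missing."""
    df = _read_tsv(path)
    return df.pivot(index="subject_id", columns="snp_id", values="dosage")


def read_vcf_dosages(path, risk_alleles: Mapping[str, str]) -> pd.DataFrame:
    """Risk-allele dosages from a VCF, oriented to the catalog risk allele.

    Counts the risk allele per genotype; sites whose REF/ALT do not include
    the catalog risk allele are skipped.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF inputs

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    data = {}
    for var in vcf:
        sid = var.ID
        if sid not in risk_alleles:
            continue
        risk = risk_alleles[sid]
        alleles = [var.REF] + list(var.ALT)
        if risk not in alleles:
            continue
        risk_idx = alleles.index(risk)
        dos = np.full(len(subjects), np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            dos[i] = float((a == risk_idx) + (b == risk_idx))
        data[sid] = dos
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))


def write_curation_report(report, out_dir) -> None:
    """curated.tsv / dropped.tsv / review.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def cur_row(c: CuratedAssociation) -> dict:
        return {
            "snp_id": c.source.snp_id,
            "phenotype": c.source.phenotype,
            "test_snp": c.test_snp,
            "proxy_r2": c.proxy_r2,
            "strand_status": c.strand_status,
            "effect": c.source.effect,
            "trait_type": c.source.trait_type,
            "raf": c.source.raf_controls,
            "study_id": c.source.study_id,
        }

    pd.DataFrame([cur_row(c) for c in report.curated]).to_csv(out / "curated.tsv", sep="\t", index=False, na_rep=_NA)
    pd.DataFrame(
        [{"snp_id": e.snp_id, "phenotype": e.phenotype, "study_id": e.study_id, "reason": reason} for e, reason in report.dropped]
    ).to_csv(out / "dropped.tsv", sep="\t", index=False, na_rep=_NA)
    pd.DataFrame([cur_row(c) for c in report.review]).to_csv(out / "review.tsv", sep="\t", index=False, na_rep=_NA)


def write_assignments(assignments: Iterable[PhenotypeAssignment], path) -> None:
    pd.DataFrame(
        [{"subject_id": a.subject_id, "phenotype": a.phenotype, "status": a.status, "reason": a.reason} for a in assignments]
    ).to_csv(path, sep="\t", index=False, na_rep=_NA)
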