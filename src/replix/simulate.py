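"""Synthetic catalogs, cohorts and surveys with the statistical structure
the pipeline assumes.

The generator emulates a self-report replication study: Hardy-Weinberg
genotypes at stated risk-allele frequencies, binary disease from the
logit-additive per-allele odds-ratio penetrance model at stated prevalence,
reported status corrupted by case/control misreport, quantitative traits
with additive dosage effects and unit-variance noise, proxy SNPs generated
from two-locus haplotype frequencies solved to hit a target r-squared, and
survey answers including uncertain and within-phenotype inconsistent
responders.

Catalog fixtures are *self-labelling*: every generated catalog row carries
an ``expected_outcome`` column naming the curation decision it is built to
trigger (kept, kept via proxy, filtered, duplicate, LD-pruned, no proxy,
strand review), so curation can be verified against the generator's intent.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams, so every output is reproducible
and components can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .power import genotype_distributions, hwe_genotype_freqs, GenotypeModel

__all__ = [
    "AssociationSpec",
    "SimConfig",
    "default_config",
    "gen_catalog",
    "gen_cohort",
    "gen_surveys",
    "gen_interaction_data",
    "solve_haplotype_freqs",
    "sample_case_control_counts",
]


@dataclass(frozen=True)
class AssociationSpec:
    snp_id: str
    phenotype: str
    raf: float
    effect: float  # OR for binary, beta for quantitative
    prevalence: float = 0.05
    trait_type: str = "binary"
    class_label: str = "other"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_subjects: int = 20_000
    associations: tuple[AssociationSpec, ...] = ()
    e_case: float = 0.05
    e_control: float = 0.05
    proxy_r2: tuple[float, ...] = (0.6,)
    p_uncertain: float = 0.05
    p_inconsistent: float = 0.01
    # logistic model for the risk-report interaction data:
    # (intercept, risk coefficient, availability coefficient, interaction)
    interaction_spec: tuple[float, float, float, float] = (-1.0, 1.0, 0.0, 0.0)

    def stream(self, name: str) -> np.random.Generator:
        """Named, deterministic substream of the run's seed."""
        h = int.from_bytes(name.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence(entropy=(self.seed, h)))


def default_config(seed: int = 0, n_subjects: int = 20_000) -> SimConfig:
    """A catalog resembling a typical replication panel: modest per-allele
    odds ratios (1.1-1.5), common risk alleles, prevalences 1-20%."""
    specs = []
    raf_cycle = [0.1, 0.2, 0.3, 0.4, 0.5]
    or_cycle = [1.1, 1.2, 1.3, 1.5]
    prev_cycle = [0.01, 0.05, 0.1, 0.2]
    classes = ["autoimmune", "cancer", "metabolic", "cardio"]
    for i in range(16):
        specs.append(
            AssociationSpec(
                snp_id=f"rs{1000 + i}",
                phenotype=f"disease_{classes[i % 4]}_{i}",
                raf=raf_cycle[i % 5],
                effect=or_cycle[i % 4],
                prevalence=prev_cycle[i % 4],
                class_label=classes[i % 4],
            )
        )
    specs.append(AssociationSpec("rs2000", "trait_q1", 0.3, 0.15, trait_type="quantitative", class_label="quant"))
    specs.append(AssociationSpec("rs2001", "trait_q2", 0.4, -0.10, trait_type="quantitative", class_label="quant"))
    return SimConfig(seed=seed, n_subjects=n_subjects, associations=tuple(specs))


# ---------------------------------------------------------------------------
# two-locus haplotype machinery for proxy SNPs


def solve_haplotype_freqs(p_a: float, p_b: float, r2: float) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) for two loci with allele
    frequencies p_a, p_b and squared correlation ``r2`` (positive phase).

    Raises with the feasible r-squared range when the target cannot be
    reached for these frequencies.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("allele frequencies must be in (0,1)")
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must be in [0,1]")
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2_max = d_max**2 / denom
    if r2 > r2_max + 1e-12:
        raise ValueError(
            f"target r2={r2} infeasible for allele frequencies "
            f"({p_a}, {p_b}); feasible range is [0, {r2_max:.4f}]"
        )
    d = math.sqrt(r2 * denom)
    h = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    return np.clip(h, 0.0, 1.0)


def _proxy_dosage(g_a: np.ndarray, p_a: float, p_b: float, r2: float, rng: np.random.Generator) -> np.ndarray:
    """Dosages at a proxy locus given dosages at the index locus, drawn
    haplotype-by-haplotype from the solved two-locus frequencies."""
    h = solve_haplotype_freqs(p_a, p_b, r2)
    pb_given_a = h[0] / p_a  # P(B | haplotype carries A)
    pb_given_not_a = h[2] / (1 - p_a)
    n_a = g_a.astype(int)
    n_other = 2 - n_a
    return rng.binomial(n_a, pb_given_a) + rng.binomial(n_other, pb_given_not_a)


def sample_case_control_counts(
    model: GenotypeModel,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype count tables (size, 3) for reported case and control groups
    drawn from the model's (possibly misclassification-mixed) genotype
    distributions."""
    r = rng.multinomial(n_cases, model.case_dist, size=size)
    s = rng.multinomial(n_controls, model.control_dist, size=size)
    return r, s


# ---------------------------------------------------------------------------
# catalog fixtures


def gen_catalog(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Self-labelling catalog, LD, platform and reference-frequency tables.

    Per association the catalog contains the primary row plus engineered
    companions: a smaller duplicate study, an LD partner above the pruning
    threshold, and an independent partner below it.  Additional archetype
    rows exercise the significance/ancestry/effect/haplotype filters, proxy
    selection above and below the r2 threshold, and ambiguous-allele strand
    review.  ``expected_outcome`` names the curation decision each row
    should receive.
    """
    rng = config.stream("catalog")
    rows, ld_rows, plat_rows, ref_rows = [], [], [], []

    def add_platform(snp, call_rate=0.999):
        plat_rows.append({"snp_id": snp, "call_rate": call_rate})

    def base_row(snp, pheno, spec, **over):
        raf = over.pop("raf", spec.raf)
        row = {
            "snp_id": snp,
            "phenotype": pheno,
            "risk_allele": "A",
            "other_allele": "G",
            "raf": raf,
            "effect": spec.effect,
            "trait_type": spec.trait_type,
            "p_value": 10.0 ** -rng.uniform(8, 20),
            "ancestry": "European",
            "study_id": f"PMID{rng.integers(10_000_000, 30_000_000)}",
            "n_cases": int(rng.integers(1_000, 20_000)),
            "n_controls": int(rng.integers(1_000, 30_000)),
            "single_snp": True,
            "includes_cohort": False,
            "expected_outcome": "curated",
        }
        row.update(over)
        return row

    for i, spec in enumerate(config.associations):
        main = base_row(spec.snp_id, spec.phenotype, spec)
        # keep reported and reference frequencies on the same side of the
        # 0.35/0.65 match band so unambiguous main rows confirm
        raf = spec.raf if spec.raf < 0.35 else 0.2
        main["raf"] = raf
        rows.append(main)
        add_platform(spec.snp_id)
        ref_rows.append({"snp_id": spec.snp_id, "ref_freq": min(max(raf + 0.02, 0.01), 0.34)})

        if i % 3 == 0:
            dup = base_row(spec.snp_id, spec.phenotype, spec)
            dup["n_cases"] = max(1, main["n_cases"] - 500)
            dup["expected_outcome"] = "duplicate"
            rows.append(dup)
        if i % 3 == 1:
            partner = f"{spec.snp_id}_ld"
            pr = base_row(partner, spec.phenotype, spec, raf=main["raf"])
            pr["study_id"] = main["study_id"]
            pr["p_value"] = main["p_value"] * 10  # larger p loses within-study
            pr["expected_outcome"] = "ld_pruned"
            rows.append(pr)
            add_platform(partner)
            ld_rows.append({"snp_a": spec.snp_id, "snp_b": partner, "r2": 0.3})
            ref_rows.append({"snp_id": partner, "ref_freq": min(max(main["raf"] + 0.02, 0.01), 0.34)})
        if i % 3 == 2:
            indep = f"{spec.snp_id}_indep"
            pr = base_row(indep, spec.phenotype, spec, raf=main["raf"])
            pr["expected_outcome"] = "curated"
            rows.append(pr)
            add_platform(indep)
            ld_rows.append({"snp_a": spec.snp_id, "snp_b": indep, "r2": 0.05})
            ref_rows.append({"snp_id": indep, "ref_freq": min(max(main["raf"] + 0.02, 0.01), 0.34)})

    if config.associations:
        spec = config.associations[0]
        archetypes = [
            base_row("rs9000", "arch_weak_p", spec, raf=0.2, p_value=1e-6, expected_outcome="filtered"),
            base_row("rs9001", "arch_no_effect", spec, raf=0.2, effect=None, expected_outcome="filtered"),
            base_row("rs9002", "arch_asian", spec, raf=0.2, ancestry="East Asian", expected_outcome="filtered"),
            base_row("rs9003", "arch_haplotype", spec, raf=0.2, single_snp=False, expected_outcome="filtered"),
            base_row("rs9004", "arch_own_cohort", spec, raf=0.2, includes_cohort=True, expected_outcome="filtered"),
            base_row("rs9005", "arch_proxy_ok", spec, raf=0.2, expected_outcome="curated_proxy"),
            base_row("rs9006", "arch_proxy_gone", spec, raf=0.2, expected_outcome="no_proxy"),
            base_row("rs9007", "arch_ambiguous", spec, raf=0.2, risk_allele="A", other_allele="T", expected_outcome="review"),
            base_row("rs9008", "arch_lowcall", spec, raf=0.2, expected_outcome="curated_proxy"),
        ]
        rows.extend(archetypes)
        for snp in ("rs9000", "rs9001", "rs9002", "rs9003", "rs9004", "rs9007"):
            add_platform(snp)
            ref_rows.append({"snp_id": snp, "ref_freq": 0.22})
        # rs9005 off platform, good proxy on platform
        proxy_r2 = config.proxy_r2[0] if config.proxy_r2 else 0.6
        add_platform("rs9005_proxy")
        ld_rows.append({"snp_a": "rs9005", "snp_b": "rs9005_proxy", "r2": proxy_r2})
        ref_rows.append({"snp_id": "rs9005", "ref_freq": 0.22})
        # rs9006 off platform, only a weak proxy
        add_platform("rs9006_proxy")
        ld_rows.append({"snp_a": "rs9006", "snp_b": "rs9006_proxy", "r2": 0.4})
        ref_rows.append({"snp_id": "rs9006", "ref_freq": 0.22})
        # rs9008 on platform but badly called; rescued by proxy
        add_platform("rs9008", call_rate=0.95)
        add_platform("rs9008_proxy")
        ld_rows.append({"snp_a": "rs9008", "snp_b": "rs9008_proxy", "r2": 0.8})
        ref_rows.append({"snp_id": "rs9008", "ref_freq": 0.22})

    catalog = pd.DataFrame(rows)
    ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"])
    platform = pd.DataFrame(plat_rows).drop_duplicates("snp_id")
    reference = pd.DataFrame(ref_rows).drop_duplicates("snp_id")
    return {"catalog": catalog, "ld": ld, "platform": platform, "reference": reference}


# ---------------------------------------------------------------------------
# cohort


def gen_cohort(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Genotypes, true/reported phenotypes, quantitative traits, proxy
    dosages and covariates for ``n_subjects`` subjects.

    Binary disease is drawn from the penetrance model at each
    association's prevalence; reported status flips true cases to reported
    controls with probability ``e_case`` and true controls to reported
    cases with probability ``e_control``.  Quantitative traits are
    ``beta * dosage + N(0,1)`` noise.  Each association in
    ``config.proxy_r2`` order gets a companion ``<snp>_proxy`` column
    generated from the solved two-locus haplotype frequencies.
    """
    n = config.n_subjects
    subjects = [f"S{i:06d}" for i in range(n)]
    geno = {}
    pheno_rows = {}
    trait_rows = {}

    for k, spec in enumerate(config.associations):
        rng = config.stream(f"cohort:{spec.snp_id}")
        g = rng.choice(3, size=n, p=hwe_genotype_freqs(spec.raf))
        geno[spec.snp_id] = g
        if spec.trait_type == "binary":
            model = genotype_distributions(spec.raf, spec.effect, spec.prevalence)
            true = rng.random(n) < model.penetrances[g]
            reported = true.copy()
            flip_case = true & (rng.random(n) < config.e_case)
            flip_ctrl = ~true & (rng.random(n) < config.e_control)
            reported[flip_case] = False
            reported[flip_ctrl] = True
            pheno_rows[spec.phenotype] = {"true": true, "reported": reported}
        else:
            trait_rows[spec.phenotype] = spec.effect * g + rng.standard_normal(n)
        if k < len(config.proxy_r2):
            prng = config.stream(f"proxy:{spec.snp_id}")
            geno[f"{spec.snp_id}_proxy"] = _proxy_dosage(g, spec.raf, spec.raf, config.proxy_r2[k], prng)

    crng = config.stream("covariates")
    covariates = pd.DataFrame(
        {
            "subject_id": subjects,
            "age": crng.integers(20, 81, size=n),
            "sex": crng.choice(["male", "female"], size=n, p=[0.58, 0.42]),
            "smoker": crng.random(n) < 0.3,
            **{f"pc{i + 1}": crng.standard_normal(n) for i in range(5)},
            "results_available": crng.random(n) < 0.5,
            "predicted_risk": crng.standard_normal(n) * 0.5,
        }
    )

    genotypes = pd.DataFrame({"subject_id": subjects, **geno})
    phen = pd.DataFrame({"subject_id": subjects})
    for pheno, d in pheno_rows.items():
        phen[f"{pheno}__true"] = d["true"]
        phen[pheno] = d["reported"]
    for pheno, y in trait_rows.items():
        phen[pheno] = y
    return {"genotypes": genotypes, "phenotypes": phen, "covariates": covariates}


def gen_surveys(config: SimConfig, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Two-question survey responses per binary phenotype.

    Ordinary responders answer both questions consistently with their
    reported status; a ``p_uncertain`` fraction answer only "not sure", and
    a ``p_inconsistent`` fraction answer yes to one question and no to the
    other (and should be excluded by assignment).
    """
    rows = []
    binary_phenos = [c for c in phenotypes.columns if c not in ("subject_id",) and not c.endswith("__true") and phenotypes[c].dtype == bool]
    for pheno in binary_phenos:
        rng = config.stream(f"survey:{pheno}")
        status = phenotypes[pheno].to_numpy()
        subjects = phenotypes["subject_id"].to_numpy()
        u = rng.random(status.size)
        q1, q2 = f"q_{pheno}_1", f"q_{pheno}_2"
        for sid, is_case, ui in zip(subjects, status, u):
            if ui < config.p_uncertain:
                rows.append((sid, q1, "uncertain", None))
                rows.append((sid, q2, "declined", None))
            elif ui < config.p_uncertain + config.p_inconsistent:
                rows.append((sid, q1, "affirmative", None))
                rows.append((sid, q2, "negative", None))
            else:
                ans = "affirmative" if is_case else "negative"
                onset = int(rng.integers(5, 70)) if is_case else None
                rows.append((sid, q1, ans, onset))
                rows.append((sid, q2, ans, onset))
    return pd.DataFrame(rows, columns=["subject_id", "question_id", "answer", "onset_age"])


def gen_interaction_data(config: SimConfig, n: int | None = None) -> pd.DataFrame:
    """Data for the risk-report interaction regression, simulated from the
    logistic model in ``config.interaction_spec`` plus weak age/sex/PC
    effects."""
    rng = config.stream("interaction")
    n = n or config.n_subjects
    b0, b_risk, b_avail, b_int = config.interaction_spec
    risk = rng.standard_normal(n)
    avail = rng.random(n) < 0.5
    age = rng.integers(20, 81, size=n)
    sex = rng.random(n) < 0.5
    pcs = rng.standard_normal((n, 5))
    logit = b0 + b_risk * risk + b_avail * avail + b_int * risk * avail
    logit = logit + 0.005 * (age - 50) + 0.1 * sex + pcs @ np.full(5, 0.02)
    status = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    df = pd.DataFrame(
        {
            "status": status.astype(int),
            "predicted_risk": risk,
            "results_available": avail.astype(int),
            "age": age,
            "sex": sex.astype(int),
        }
    )
    for i in range(5):
        df[f"pc{i + 1}"] = pcs[:, i]
    return df
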