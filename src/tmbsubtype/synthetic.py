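"""Synthetic tumor-cohort generator.

Emulates the statistical structure the analysis pipeline assumes: a
right-skewed TMB distribution with a high-burden subpopulation, a
smoking-like C>A signature whose share of mutations grows with TMB, one
gene whose mutation probability scales with TMB, clinical covariates
correlated with TMB, and exponential disease-free survival with a subtype
hazard effect.  Every latent draw is recorded in a ground-truth bundle so
parameter-recovery tests can compare pipeline output against it.

Contexts are emitted directly in the mutation table (no reference genome);
positions are arbitrary unique placeholders on one contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_cohort import (
    AgeGroup,
    ClinicalRecord,
    CohortTable,
    Metastasis,
    MutationRecord,
    Smoking,
    Stage,
    VariantClass,
    write_clinical,
    write_maf,
)
from .signatures import CATEGORIES_96, load_default_catalog, reverse_complement

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GenePanelEntry:
    base_prob: float
    tmb_slope: float = 0.0  # logit-scale slope on standardized log TMB


def _default_panel() -> dict[str, GenePanelEntry]:
    panel = {
        # mutation probability rises with TMB (the "RYR2-like" gene)
        "RYR2L": GenePanelEntry(base_prob=0.20, tmb_slope=3.0),
        # leans toward low-TMB samples (the "EGFR-like" gene)
        "EGFRL": GenePanelEntry(base_prob=0.28, tmb_slope=-0.8),
    }
    base = [0.22, 0.18, 0.15, 0.12, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05]
    for i, p in enumerate(base):
        panel[f"PNL{i + 1:02d}"] = GenePanelEntry(base_prob=p)
    return panel


@dataclass
class SimulationParams:
    n_samples: int = 101
    # two-component lognormal TMB mixture, modes near 60 and 400
    tmb_low_logmu: float = 4.454
    tmb_low_logsd: float = 0.55
    tmb_high_logmu: float = 6.242
    tmb_high_logsd: float = 0.45
    weight_high: float = 0.33
    tmb_range: tuple[int, int] = (7, 1126)
    indel_fraction: float = 0.05
    synonymous_fraction: float = 0.30
    # generating signature profiles (drawn from the packaged catalog)
    signature_names: tuple[str, ...] = ("Signature 2", "Signature 4", "Signature 6")
    smoking_signature: str = "Signature 4"
    # smoking-like exposure fraction: logistic in log TMB
    exposure_slope: float = 2.5
    exposure_midpoint_tmb: float = 150.0
    exposure_floor: float = 0.05
    exposure_ceiling: float = 0.90
    gene_panel: dict[str, GenePanelEntry] = field(default_factory=_default_panel)
    n_background_genes: int = 300
    panel_extra_weight: float = 0.5  # panel genes' weight in filler assignment
    # clinical couplings
    smoking_from_exposure_slope: float = 0.8
    smoking_base: float = 0.15
    age_mean: float = 58.0
    age_sd: float = 8.0
    age_tmb_shift: float = 8.0
    stage_late_base: float = 0.30
    stage_late_high_shift: float = 0.15
    metastasis_base: float = 0.15
    metastasis_high_shift: float = 0.10
    # exponential DFS with a hazard effect for the high-TMB component
    baseline_hazard: float = 1.0 / 36.0  # per month
    hazard_ratio: float = 2.0
    censor_max: float = 60.0

    def validate(self) -> None:
        if not 0 <= self.weight_high <= 1:
            raise ValueError("weight_high must be in [0, 1]")
        if not 0 <= self.indel_fraction < 1:
            raise ValueError("indel_fraction must be in [0, 1)")
        if not 0 <= self.synonymous_fraction < 1:
            raise ValueError("synonymous_fraction must be in [0, 1)")
        for g, e in self.gene_panel.items():
            if not 0 < e.base_prob < 1:
                raise ValueError(f"panel gene {g}: base_prob must be in (0, 1)")
        if self.smoking_signature not in self.signature_names:
            raise ValueError("smoking_signature must be one of signature_names")
        if not 0 < self.exposure_ceiling <= 1:
            raise ValueError("exposure_ceiling must be in (0, 1]")


@dataclass
class GroundTruth:
    """Latent draws behind a generated cohort."""

    samples: pd.DataFrame  # per-sample component, tmb, exposures, clinical latents
    gene_indicators: pd.DataFrame  # panel genes x samples, 0/1 intended indicators
    signature_counts: pd.DataFrame  # generating signatures x samples, SNV counts
    profiles: pd.DataFrame  # 96 x K generating profiles
    params: SimulationParams


def _category_record(
    sample_id: str, gene: str, category: str, pos: int,
    variant_class: VariantClass, flip: bool,
) -> MutationRecord:
    five, sub, three = category[0], category[2:5], category[6]
    ref, alt = sub[0], sub[2]
    context = five + ref + three
    if flip:  # represent on the purine strand to exercise folding
        context = reverse_complement(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return MutationRecord(
        sample_id=sample_id, gene=gene, chrom="chr1", pos=pos,
        ref=ref, alt=alt, variant_class=variant_class, context=context,
    )


_NONSYN_CLASSES = (
    VariantClass.MISSENSE, VariantClass.NONSENSE, VariantClass.SPLICE_SITE,
)
_NONSYN_PROBS = (0.85, 0.10, 0.05)


def generate_cohort(
    params: SimulationParams | None = None,
    seed: int | None = None,
    null: bool = False,
) -> tuple[CohortTable, GroundTruth]:
    """Draw a full synthetic cohort plus its ground-truth bundle.

    With ``null=True`` every coupling is severed: signature exposures, gene
    indicators, clinical covariates and hazards are independent of TMB.
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(seed)

    catalog = load_default_catalog()
    profiles = np.column_stack([catalog.profile(n) for n in params.signature_names])
    profiles = profiles / profiles.sum(axis=0)  # exact unit columns for sampling
    k = profiles.shape[1]
    smoke_ix = params.signature_names.index(params.smoking_signature)
    other_ix = [i for i in range(k) if i != smoke_ix]

    n = params.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    lo, hi = params.tmb_range

    component = rng.random(n) < params.weight_high
    if null:
        component = rng.random(n) < params.weight_high  # still drawn, but unused below
    logmu = np.where(component, params.tmb_high_logmu, params.tmb_low_logmu)
    logsd = np.where(component, params.tmb_high_logsd, params.tmb_low_logsd)
    tmb = np.clip(np.round(np.exp(rng.normal(logmu, logsd))).astype(int), lo, hi)

    # smoking-like exposure fraction
    if null:
        frac_smoke = np.full(n, 0.40)
    else:
        z = params.exposure_slope * (np.log(tmb) - np.log(params.exposure_midpoint_tmb))
        frac_smoke = params.exposure_floor + (
            params.exposure_ceiling - params.exposure_floor
        ) * _sigmoid(z)
    exposures = np.zeros((n, k))
    exposures[:, smoke_ix] = frac_smoke
    # per-sample jitter keeps the non-smoking processes linearly independent
    rest_split = rng.dirichlet(np.full(len(other_ix), 3.0), size=n)
    exposures[:, other_ix] = (1 - frac_smoke)[:, None] * rest_split

    panel_genes = list(params.gene_panel)
    bg_genes = [f"BG{i + 1:04d}" for i in range(params.n_background_genes)]
    z_tmb = (np.log(tmb) - np.log(params.exposure_midpoint_tmb))  # centered log TMB

    mutations: list[MutationRecord] = []
    indicator = np.zeros((len(panel_genes), n), dtype=np.int8)
    sig_counts = np.zeros((k, n), dtype=int)
    clin_rows: list[ClinicalRecord] = []
    samp_frames = []
    pos_counter = 1

    filler_weights = np.concatenate([
        np.ones(len(bg_genes)),
        np.full(len(panel_genes), params.panel_extra_weight),
    ])
    filler_weights = filler_weights / filler_weights.sum()
    filler_names = bg_genes + panel_genes

    for i, sid in enumerate(sample_ids):
        m = int(tmb[i])
        n_indel = int(round(params.indel_fraction * m))
        n_snv = m - n_indel

        # per-SNV generating signature, then category from that profile
        sig_of = rng.choice(k, size=n_snv, p=exposures[i])
        for kk in range(k):
            sig_counts[kk, i] = int((sig_of == kk).sum())
        cats = np.empty(n_snv, dtype=int)
        for kk in range(k):
            mask = sig_of == kk
            if mask.any():
                cats[mask] = rng.choice(96, size=int(mask.sum()), p=profiles[:, kk])

        # intended panel indicators
        for gi, g in enumerate(panel_genes):
            entry = params.gene_panel[g]
            slope = 0.0 if null else entry.tmb_slope
            logit = np.log(entry.base_prob / (1 - entry.base_prob)) + slope * z_tmb[i]
            indicator[gi, i] = rng.random() < _sigmoid(logit)

        mutated_panel = [g for gi, g in enumerate(panel_genes) if indicator[gi, i]]
        if len(mutated_panel) > n_snv:  # cannot honor more indicators than SNVs
            dropped = mutated_panel[n_snv:]
            for g in dropped:
                indicator[panel_genes.index(g), i] = 0
            mutated_panel = mutated_panel[:n_snv]

        # class draws for every SNV; guaranteed panel SNVs are forced nonsyn
        classes = []
        for j in range(n_snv):
            if rng.random() < params.synonymous_fraction:
                classes.append(VariantClass.SYNONYMOUS)
            else:
                classes.append(
                    _NONSYN_CLASSES[rng.choice(3, p=_NONSYN_PROBS)]
                )
        flips = rng.random(n_snv) < 0.5
        genes_for_snv = list(rng.choice(
            len(filler_names), size=n_snv, p=filler_weights
        ))
        for j, g in enumerate(mutated_panel):  # first SNVs carry the indicators
            genes_for_snv[j] = len(bg_genes) + panel_genes.index(g)
            classes[j] = VariantClass.MISSENSE

        for j in range(n_snv):
            mutations.append(_category_record(
                sid, filler_names[genes_for_snv[j]], CATEGORIES_96[cats[j]],
                pos_counter, classes[j], bool(flips[j]),
            ))
            pos_counter += 1

        for _ in range(n_indel):
            gene = filler_names[rng.choice(len(filler_names), p=filler_weights)]
            frameshift = rng.random() < 0.7
            mutations.append(MutationRecord(
                sample_id=sid, gene=gene, chrom="chr1", pos=pos_counter,
                ref="AT", alt="A",
                variant_class=(
                    VariantClass.FRAMESHIFT_INDEL if frameshift
                    else VariantClass.NONFRAMESHIFT_INDEL
                ),
                context=None,
            ))
            pos_counter += 1

        # clinical covariates
        if null:
            p_smoke = 0.45
            age = rng.normal(params.age_mean + 4.0, params.age_sd)
            p_late = params.stage_late_base
            p_met = params.metastasis_base
            hazard = params.baseline_hazard
        else:
            p_smoke = min(
                0.98, params.smoking_base
                + params.smoking_from_exposure_slope * frac_smoke[i]
            )
            age = rng.normal(
                params.age_mean + params.age_tmb_shift * _sigmoid(z_tmb[i]),
                params.age_sd,
            )
            p_late = params.stage_late_base + (
                params.stage_late_high_shift if component[i] else 0.0
            )
            p_met = params.metastasis_base + (
                params.metastasis_high_shift if component[i] else 0.0
            )
            hazard = params.baseline_hazard * (
                params.hazard_ratio if component[i] else 1.0
            )
        smoking = Smoking.SMOKER if rng.random() < p_smoke else Smoking.NON_SMOKER
        age = float(np.clip(round(age, 1), 30.0, 95.0))
        stage = Stage.LATE if rng.random() < p_late else Stage.EARLY
        metastasis = Metastasis.YES if rng.random() < p_met else Metastasis.NO
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.uniform(0.0, params.censor_max)
        dfs_time = float(round(min(t_event, t_censor), 2))
        dfs_event = bool(t_event <= t_censor)
        clin_rows.append(ClinicalRecord(
            sample_id=sid, age=age,
            age_group=AgeGroup.AT_LEAST65 if age >= 65 else AgeGroup.UNDER65,
            smoking=smoking, stage=stage, metastasis=metastasis,
            dfs_time=dfs_time, dfs_event=dfs_event,
        ))
        samp_frames.append({
            "sample_id": sid,
            "component": "high" if component[i] else "low",
            "tmb": m,
            "n_snv": n_snv,
            "n_indel": n_indel,
            **{f"exposure[{nm}]": exposures[i, kk]
               for kk, nm in enumerate(params.signature_names)},
            "hazard": hazard,
        })

    cohort = CohortTable(
        mutations=mutations, clinical=clin_rows, sample_ids=sample_ids
    )
    truth = GroundTruth(
        samples=pd.DataFrame(samp_frames).set_index("sample_id"),
        gene_indicators=pd.DataFrame(
            indicator, index=panel_genes, columns=sample_ids
        ),
        signature_counts=pd.DataFrame(
            sig_counts, index=list(params.signature_names), columns=sample_ids
        ),
        profiles=pd.DataFrame(
            profiles, index=list(CATEGORIES_96), columns=list(params.signature_names)
        ),
        params=params,
    )
    return cohort, truth


def generate_null_cohort(
    params: SimulationParams | None = None, seed: int | None = None
) -> tuple[CohortTable, GroundTruth]:
    """Cohort with all couplings severed, for type-I-error suites."""
    return generate_cohort(params, seed, null=True)


def write_cohort(
    cohort: CohortTable, truth: GroundTruth | None, outdir: str | Path
) -> dict[str, Path]:
    """Write MAF-like, clinical, and ground-truth TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": outdir / "mutations.maf.tsv",
        "clinical": outdir / "clinical.tsv",
    }
    write_maf(cohort.mutations, paths["maf"])
    write_clinical(cohort.clinical, paths["clinical"])
    with open(outdir / "samples.txt", "w") as fh:
        fh.write("\n".join(cohort.sample_ids) + "\n")
    paths["samples"] = outdir / "samples.txt"
    if truth is not None:
        paths["truth_samples"] = outdir / "truth_samples.tsv"
        truth.samples.to_csv(paths["truth_samples"], sep="\t")
        paths["truth_gene_indicators"] = outdir / "truth_gene_indicators.tsv"
        truth.gene_indicators.to_csv(paths["truth_gene_indicators"], sep="\t")
        paths["truth_signature_counts"] = outdir / "truth_signature_counts.tsv"
        truth.signature_counts.to_csv(paths["truth_signature_counts"], sep="\t")
    return paths
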