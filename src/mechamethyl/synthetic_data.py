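"""Synthetic paired methylation / expression / clinical data with planted truth.

Emulates the study design this pipeline targets: two neo-cartilage organoid
models (spherical constructs and cylindrical agarose-embedded constructs),
26 mechanically loaded samples versus 27 unloaded controls in total, EPIC-like
beta values, a subset of probes with genotype-like trimodal patterns, sporadic
detection failures, loading effects planted on the M (logit) scale with
between-model heterogeneity, positional probe clusters so that region calling
is exercised, and expression counts in which a subset of DM-mapped genes carry
a true fold change.  Every planted feature is returned in a :class:`TruthSet`
so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidDesignError
from .qc_normalization import MethylationDataset, m_to_beta

CHROMOSOMES = ("chr1", "chr2", "chr3", "chr4")
CHROM_LENGTH = 10_000_000

CHROMATIN_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "Enh", "EnhG", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)
_STATE_WEIGHTS = np.array(
    [0.05, 0.06, 0.02, 0.06, 0.12, 0.10, 0.03, 0.02,
     0.04, 0.02, 0.02, 0.03, 0.05, 0.08, 0.30]
)

REGION_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "ExonBnd", "3'UTR", "Body")
_CATEGORY_WEIGHTS = np.array([0.10, 0.15, 0.12, 0.06, 0.07, 0.12, 0.38])

MODELS = ("spherical", "cylindrical")


@dataclass
class StudyDesign:
    """Sample-size layout of the two-model loading experiment.

    Defaults place 13 loaded / 13 control samples in the spherical model and
    13 / 14 in the cylindrical model (26 loaded vs 27 control in total).
    """

    n_loaded_spherical: int = 13
    n_control_spherical: int = 13
    n_loaded_cylindrical: int = 13
    n_control_cylindrical: int = 14
    n_probes: int = 5000
    n_genes: int = 500
    seed: int = 0

    def validate(self) -> None:
        arms = (
            self.n_loaded_spherical, self.n_control_spherical,
            self.n_loaded_cylindrical, self.n_control_cylindrical,
        )
        if any(a < 2 for a in arms):
            raise InvalidDesignError("every arm needs >= 2 samples")
        if self.n_probes < 0 or self.n_genes < 0:
            raise InvalidDesignError("n_probes and n_genes must be non-negative")
        if self.n_probes < self.n_genes:
            raise InvalidDesignError("n_probes must be >= n_genes")

    def arm_sizes(self, model: str) -> tuple[int, int]:
        if model == "spherical":
            return self.n_loaded_spherical, self.n_control_spherical
        return self.n_loaded_cylindrical, self.n_control_cylindrical


@dataclass
class EffectSpec:
    """Planted effect structure.

    ``delta_m`` is the loading effect per DM probe on the M (log2-logit)
    scale; ``noise_sd_m`` the residual SD on that scale (0.5 is typical of
    array M-values); ``tau_model`` the between-model SD of the effect.
    """

    frac_dm: float = 0.05
    delta_m: float = 1.0
    tau_model: float = 0.25
    frac_dmr_clustered: float = 0.5
    frac_linked_genes: float = 0.3
    expr_lfc: float = 1.0
    frac_snp_like: float = 0.05
    frac_fail: float = 0.002
    noise_sd_m: float = 0.5
    nb_dispersion: float = 0.1

    def validate(self) -> None:
        fracs = (
            self.frac_dm, self.frac_dmr_clustered, self.frac_linked_genes,
            self.frac_snp_like, self.frac_fail,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise InvalidDesignError("fractions must lie in [0, 1]")
        if self.noise_sd_m <= 0:
            raise InvalidDesignError("noise_sd_m must be positive")


@dataclass
class TruthSet:
    """Everything the generator planted, keyed for exact recovery scoring."""

    dm_probes: dict = field(default_factory=dict)        # probe_id -> signed delta_m
    linked_genes: dict = field(default_factory=dict)     # gene -> planted log2 FC
    snp_like_probes: set = field(default_factory=set)
    failing_cells: set = field(default_factory=set)      # (probe_id, sample_id)
    planted_dmrs: list = field(default_factory=list)     # (chrom, start, end)
    clinical_slope: dict = field(default_factory=dict)   # cpg -> true KL coefficient

    def to_json(self) -> str:
        d = asdict(self)
        d["snp_like_probes"] = sorted(self.snp_like_probes)
        d["failing_cells"] = sorted(list(c) for c in self.failing_cells)
        return json.dumps(d, indent=2)


@dataclass
class CountMatrix:
    """Gene-by-sample RNA-seq counts plus the matching sample sheet."""

    counts: pd.DataFrame
    samples: pd.DataFrame


def _rng(design_seed: int, seed: int | None, salt: int) -> np.random.Generator:
    base = design_seed if seed is None else seed
    return np.random.default_rng((int(base) + salt) % (2**31))


def generate_probe_annotation(design: StudyDesign, seed: int | None = None) -> pd.DataFrame:
    """Annotation table: probe_id, chrom, pos, chrom_state, genes, categories.

    Positions are strictly increasing within each chromosome and mix tight
    CpG-island-like clusters (4-8 probes, 80-400 bp gaps) with dispersed
    probes, so that region scanning has realistic material.  ``genes`` and
    ``categories`` are ';'-joined parallel lists (empty string = unmapped).
    """
    design.validate()
    rng = _rng(design.seed, seed, salt=11)
    if design.n_probes == 0:
        return pd.DataFrame(
            columns=["probe_id", "chrom", "pos", "chrom_state", "genes", "categories"]
        ).set_index("probe_id")

    per_chrom = np.full(len(CHROMOSOMES), design.n_probes // len(CHROMOSOMES))
    per_chrom[: design.n_probes % len(CHROMOSOMES)] += 1

    rows: list[tuple] = []
    gene_positions: dict[str, list[tuple[str, int]]] = {c: [] for c in CHROMOSOMES}
    probe_counter = 0
    for chrom, n_chrom in zip(CHROMOSOMES, per_chrom):
        pos = int(rng.integers(10_000, 50_000))
        placed = 0
        while placed < n_chrom:
            remaining = n_chrom - placed
            make_cluster = remaining >= 4 and rng.random() < 0.35
            size = int(rng.integers(4, 9)) if make_cluster else 1
            size = min(size, remaining)
            for j in range(size):
                if j > 0:
                    pos += int(rng.integers(80, 400))
                if pos >= CHROM_LENGTH:
                    raise InvalidDesignError(
                        "n_probes too large for the synthetic genome"
                    )
                rows.append((f"cg{probe_counter:08d}", chrom, pos))
                probe_counter += 1
                placed += 1
            pos += int(rng.integers(1500, 12_000))

    ann = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    ann["chrom_state"] = rng.choice(
        CHROMATIN_STATES, size=len(ann), p=_STATE_WEIGHTS / _STATE_WEIGHTS.sum()
    )

    # genes: TSS positions spread over the chromosomes, proportional to probes
    n_gene_chrom = np.full(len(CHROMOSOMES), design.n_genes // len(CHROMOSOMES))
    n_gene_chrom[: design.n_genes % len(CHROMOSOMES)] += 1
    gene_id = 0
    for chrom, ng in zip(CHROMOSOMES, n_gene_chrom):
        tss = np.sort(rng.integers(1, CHROM_LENGTH, size=ng))
        for t in tss:
            gene_positions[chrom].append((f"GENE{gene_id:05d}", int(t)))
            gene_id += 1

    genes_col, cats_col = [], []
    cat_p = _CATEGORY_WEIGHTS / _CATEGORY_WEIGHTS.sum()
    for chrom, pos in zip(ann["chrom"], ann["pos"]):
        glist = gene_positions[chrom]
        names: list[str] = []
        if glist and rng.random() < 0.83:
            tss_arr = np.array([g[1] for g in glist])
            nearest = int(np.argmin(np.abs(tss_arr - pos)))
            names.append(glist[nearest][0])
            if len(glist) > 1 and rng.random() < 0.1:
                order = np.argsort(np.abs(tss_arr - pos))
                names.append(glist[int(order[1])][0])
        cats = [str(rng.choice(REGION_CATEGORIES, p=cat_p)) for _ in names]
        genes_col.append(";".join(names))
        cats_col.append(";".join(cats))
    ann["genes"] = genes_col
    ann["categories"] = cats_col
    return ann.set_index("probe_id")


def _positional_clusters(ann: pd.DataFrame, max_gap: int = 1000, min_size: int = 3):
    """Maximal runs of consecutive probes with inter-probe gaps < max_gap."""
    clusters = []
    for chrom, sub in ann.sort_values(["chrom", "pos"]).groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] >= max_gap:
                if i - start >= min_size:
                    clusters.append((chrom, list(ids[start:i])))
                start = i
    return clusters


def generate_methylation_experiment(
    design: StudyDesign,
    spec: EffectSpec,
    annotation: pd.DataFrame,
    seed: int | None = None,
) -> tuple[dict[str, MethylationDataset], TruthSet]:
    """Two per-model methylation datasets plus the planted TruthSet.

    M values follow ``mu_probe + (delta + model_shift) * loaded + noise`` with
    ``model_shift ~ N(0, tau_model)`` drawn per probe per model; SNP-like
    probes instead draw betas trimodally near {0.05, 0.5, 0.95} with
    Hardy-Weinberg cluster weights.
    """
    design.validate()
    spec.validate()
    if len(annotation) != design.n_probes:
        raise InvalidDesignError("annotation does not cover n_probes")
    rng = _rng(design.seed, seed, salt=23)
    probes = annotation.index.to_numpy()
    n = len(probes)
    truth = TruthSet()

    n_snp = int(round(spec.frac_snp_like * n))
    snp_idx = rng.choice(n, size=n_snp, replace=False) if n_snp else np.array([], dtype=int)
    snp_mask = np.zeros(n, dtype=bool)
    snp_mask[snp_idx] = True
    truth.snp_like_probes = set(probes[snp_mask])

    # DM probes: a slice of the budget goes to whole positional clusters
    n_dm = int(round(spec.frac_dm * n))
    delta = np.zeros(n)
    probe_pos = {p: i for i, p in enumerate(probes)}
    dm_mask = np.zeros(n, dtype=bool)
    if n_dm:
        cluster_budget = int(round(spec.frac_dmr_clustered * n_dm))
        clusters = [
            (chrom, members)
            for chrom, members in _positional_clusters(annotation)
            if not any(m in truth.snp_like_probes for m in members)
        ]
        rng.shuffle(clusters)
        used = 0
        for chrom, members in clusters:
            if used + len(members) > cluster_budget + 2:
                continue
            sign = rng.choice([-1.0, 1.0])
            for m in members:
                dm_mask[probe_pos[m]] = True
                delta[probe_pos[m]] = sign * spec.delta_m
            sub = annotation.loc[members]
            truth.planted_dmrs.append(
                (chrom, int(sub["pos"].min()), int(sub["pos"].max()))
            )
            used += len(members)
            if used >= cluster_budget:
                break
        free = np.flatnonzero(~dm_mask & ~snp_mask)
        n_extra = max(0, n_dm - int(dm_mask.sum()))
        extra = rng.choice(free, size=min(n_extra, len(free)), replace=False)
        dm_mask[extra] = True
        delta[extra] = rng.choice([-1.0, 1.0], size=len(extra)) * spec.delta_m
    truth.dm_probes = {p: float(delta[i]) for i, p in enumerate(probes) if dm_mask[i]}

    # probe baselines: bimodal like real arrays, on the M scale
    comp = rng.choice(3, size=n, p=[0.4, 0.4, 0.2])
    mu = np.where(
        comp == 0, rng.normal(-4, 1, n), np.where(comp == 1, rng.normal(4, 1, n), rng.normal(0, 1.5, n))
    )

    snp_p = rng.uniform(0.2, 0.8, size=n)  # allele frequency per SNP-like probe

    datasets: dict[str, MethylationDataset] = {}
    for model in MODELS:
        n_loaded, n_control = design.arm_sizes(model)
        n_samp = n_loaded + n_control
        prefix = "sph" if model == "spherical" else "cyl"
        sample_ids = [f"{prefix}_L{i:02d}" for i in range(n_loaded)] + [
            f"{prefix}_C{i:02d}" for i in range(n_control)
        ]
        condition = ["loaded"] * n_loaded + ["control"] * n_control
        loaded_vec = np.array([1.0] * n_loaded + [0.0] * n_control)

        model_shift = rng.normal(0, spec.tau_model, size=n) * dm_mask
        effect = (delta + model_shift) * dm_mask
        m_mat = (
            mu[:, None]
            + effect[:, None] * loaded_vec[None, :]
            + rng.normal(0, spec.noise_sd_m, size=(n, n_samp))
        )
        beta = m_to_beta(m_mat)

        if n_snp:
            centers = np.array([0.05, 0.5, 0.95])
            p_alt = snp_p[snp_mask]
            hw = np.stack([p_alt**2, 2 * p_alt * (1 - p_alt), (1 - p_alt) ** 2], axis=1)
            geno = np.stack(
                [rng.choice(3, size=n_samp, p=hw[i]) for i in range(n_snp)], axis=0
            )
            snp_beta = np.clip(
                centers[geno] + rng.normal(0, 0.02, size=geno.shape), 0.001, 0.999
            )
            beta[snp_mask] = snp_beta

        detp = rng.uniform(0, 0.005, size=(n, n_samp))
        n_fail = int(round(spec.frac_fail * n * n_samp))
        if n_fail:
            # keep planted DM probes detectable so recovery is well defined
            eligible = np.flatnonzero(~dm_mask)
            cells = rng.choice(len(eligible) * n_samp, size=min(n_fail, len(eligible) * n_samp), replace=False)
            rows = eligible[cells // n_samp]
            cols = cells % n_samp
            detp[rows, cols] = rng.uniform(0.02, 1.0, size=len(rows))
            truth.failing_cells |= {
                (probes[r], sample_ids[c]) for r, c in zip(rows, cols)
            }

        samples = pd.DataFrame(
            {"sample_id": sample_ids, "model": model, "condition": condition}
        ).set_index("sample_id")
        datasets[model] = MethylationDataset(
            beta=pd.DataFrame(beta, index=annotation.index, columns=sample_ids),
            detp=pd.DataFrame(detp, index=annotation.index, columns=sample_ids),
            samples=samples,
            model_label=model,
        )

    # genes linked to expression changes: among DM-mapped genes via
    # TSS/UTR/exon categories (the categories the integration step uses)
    qualifying = {c for c in REGION_CATEGORIES if c != "Body"}
    mapped_genes: set[str] = set()
    for p in truth.dm_probes:
        row = annotation.loc[p]
        if not row["genes"]:
            continue
        for g, c in zip(row["genes"].split(";"), row["categories"].split(";")):
            if c in qualifying:
                mapped_genes.add(g)
    n_linked = int(round(spec.frac_linked_genes * len(mapped_genes)))
    linked = rng.choice(sorted(mapped_genes), size=n_linked, replace=False) if n_linked else []
    truth.linked_genes = {
        g: float(rng.choice([-1.0, 1.0]) * spec.expr_lfc) for g in linked
    }
    return datasets, truth


def generate_expression_counts(
    design: StudyDesign,
    spec: EffectSpec,
    annotation: pd.DataFrame,
    truth: TruthSet,
    seed: int | None = None,
) -> CountMatrix:
    """Negative-binomial RNA-seq counts over both models' samples.

    Linked genes have their mean multiplied by ``2 ** expr_lfc`` in loaded
    samples; library sizes vary +-30%.
    """
    design.validate()
    spec.validate()
    rng = _rng(design.seed, seed, salt=37)
    gene_ids = sorted(
        {g for gg in annotation["genes"] if gg for g in gg.split(";")}
    )
    extra = [f"GENE{j:05d}" for j in range(design.n_genes)]
    gene_ids = sorted(set(gene_ids) | set(extra))
    missing = set(truth.linked_genes) - set(gene_ids)
    if missing:
        raise InvalidDesignError(f"linked genes absent from annotation: {sorted(missing)[:5]}")

    sample_rows = []
    for model in MODELS:
        n_loaded, n_control = design.arm_sizes(model)
        prefix = "sph" if model == "spherical" else "cyl"
        for i in range(n_loaded):
            sample_rows.append((f"{prefix}_L{i:02d}", model, "loaded"))
        for i in range(n_control):
            sample_rows.append((f"{prefix}_C{i:02d}", model, "control"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "model", "condition"]
    ).set_index("sample_id")

    n_genes = len(gene_ids)
    n_samp = len(samples)
    base_mean = np.exp(rng.normal(np.log(100), 1.0, size=n_genes))
    lfc = np.array([truth.linked_genes.get(g, 0.0) for g in gene_ids])
    loaded_vec = (samples["condition"] == "loaded").to_numpy(dtype=float)
    lib = rng.uniform(0.7, 1.3, size=n_samp)
    mu = base_mean[:, None] * np.exp2(lfc[:, None] * loaded_vec[None, :]) * lib[None, :]
    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples.index),
        samples=samples,
    )


def generate_clinical_cohort(
    n_patients: int,
    cpgs: list[str],
    slopes: dict[str, float],
    seed: int = 0,
    b_bmi: float = 0.01,
    b_age: float = -0.005,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Patient table with KL-score, BMI, age and per-CpG beta values.

    Beta at each CpG is inverse-logit of a linear predictor in KL, BMI and
    age; ``slopes`` holds the true per-CpG KL coefficient on the logit scale.
    """
    if n_patients < 10:
        raise InvalidDesignError("n_patients must be >= 10")
    rng = np.random.default_rng(int(seed) % (2**31))
    kl = rng.integers(1, 5, size=n_patients)
    bmi = rng.normal(27, 4, size=n_patients)
    age = rng.normal(65, 8, size=n_patients)
    out = pd.DataFrame(
        {"kl_score": kl, "bmi": bmi, "age": age},
        index=[f"patient{i:04d}" for i in range(n_patients)],
    )
    for cpg in cpgs:
        slope = slopes.get(cpg, 0.0)
        lin = (
            rng.normal(0, 0.5)
            + slope * kl
            + b_bmi * bmi
            + b_age * age
            + rng.normal(0, noise_sd, size=n_patients)
        )
        out[cpg] = 1.0 / (1.0 + np.exp(-lin))
    out.index.name = "patient_id"
    return out
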