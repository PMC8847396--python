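"""Seeded synthetic paired-chain single-cell TCR repertoires with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: per-sample repertoires of paired TRA/TRB clones with skewed,
condition-dependent clone-size laws; Dirichlet-perturbed V-gene usage
profiles shared within a specificity group; in-frame CDR3 nucleotide
sequences with the canonical C...F flanks; per-cell transcriptional
cluster labels whose distribution shifts with clone size (a softmax model
with a log-size covariate on a designated target-cluster set);
chain-dropout / doublet contamination; and a configurable rate of public
clones copied across samples.  Everything is emitted in the 10x contig CSV
dialect plus an annotation TSV, with a manifest of all planted parameters,
and is byte-deterministic under a fixed seed.

Clonotype keys are unique by construction (CDR3 collisions are resampled),
so with zero contamination the pipeline recovers every planted clone size
exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import brentq

from ._errors import ValidationError

_CODON_TO_AA = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
_NONSTOP_CODONS = np.array(sorted(_CODON_TO_AA))
_CYS_CODONS = np.array(sorted(c for c, aa in _CODON_TO_AA.items() if aa == "C"))
_PHE_CODONS = np.array(sorted(c for c, aa in _CODON_TO_AA.items() if aa == "F"))

# Skewed default germline pools (mouse-style IMGT names).  The exact
# frequencies are arbitrary but strongly non-uniform, as real V-gene usage is.
DEFAULT_TRBV = {
    "TRBV1": 0.04, "TRBV2": 0.05, "TRBV3": 0.03, "TRBV4": 0.06, "TRBV5": 0.08,
    "TRBV12-1": 0.05, "TRBV12-2": 0.04, "TRBV13-1": 0.10, "TRBV13-2": 0.09,
    "TRBV13-3": 0.07, "TRBV14": 0.04, "TRBV15": 0.03, "TRBV16": 0.05,
    "TRBV17": 0.02, "TRBV19": 0.09, "TRBV20": 0.03, "TRBV23": 0.02,
    "TRBV26": 0.04, "TRBV29": 0.05, "TRBV31": 0.02,
}
DEFAULT_TRAV = {
    "TRAV1": 0.05, "TRAV2": 0.03, "TRAV3-3": 0.06, "TRAV4-3": 0.07,
    "TRAV5-1": 0.05, "TRAV6-3": 0.08, "TRAV7-2": 0.09, "TRAV8-1": 0.06,
    "TRAV9-1": 0.10, "TRAV10": 0.05, "TRAV12-1": 0.07, "TRAV13-1": 0.06,
    "TRAV14-1": 0.09, "TRAV16": 0.08, "TRAV21": 0.06,
}
TRBJ_GENES = ("TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-5", "TRBJ2-7")
TRAJ_GENES = ("TRAJ12", "TRAJ23", "TRAJ31", "TRAJ40", "TRAJ56")

DEFAULT_TRB_LENGTHS = {12: 0.10, 13: 0.20, 14: 0.30, 15: 0.20, 16: 0.12, 17: 0.08}
DEFAULT_TRA_LENGTHS = {10: 0.08, 11: 0.15, 12: 0.22, 13: 0.25, 14: 0.15, 15: 0.10, 16: 0.05}


def _normalized(probs: dict) -> dict:
    total = sum(probs.values())
    if total <= 0:
        raise ValidationError("probability profile must have positive mass")
    return {k: v / total for k, v in probs.items()}


@dataclass(frozen=True)
class SizeLaw:
    """Clone-size distribution on {1..max_size}.

    kind="powerlaw": P(k) proportional to k^(-param) (param = alpha > 0;
    alpha <= 1 requires a finite max_size).  kind="geometric":
    P(k) proportional to (1-param)^(k-1) * param (param = q in (0, 1]).
    """

    kind: str = "powerlaw"
    param: float = 1.8
    max_size: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("powerlaw", "geometric"):
            raise ValidationError(f"unknown size law {self.kind!r}")
        if self.kind == "powerlaw" and self.param <= 1 and self.max_size is None:
            raise ValidationError("powerlaw with alpha <= 1 needs a finite max size")
        if self.kind == "geometric" and not (0 < self.param <= 1):
            raise ValidationError("geometric q must be in (0, 1]")
        if self.max_size is not None and self.max_size < 1:
            raise ValidationError("max_size must be >= 1")

    def pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_size + 1, dtype=float)
        if self.kind == "powerlaw":
            with np.errstate(over="ignore"):
                w = k ** (-self.param)
        else:
            q = self.param
            if q == 1.0:
                w = np.zeros_like(k)
                w[0] = 1.0
            else:
                w = (1 - q) ** (k - 1) * q
        return w / w.sum()


def sample_clone_sizes(s: int, law: SizeLaw, rng: np.random.Generator) -> np.ndarray:
    """Draw *s* clone sizes i.i.d. from the truncated size law."""
    if s < 1:
        raise ValidationError("number of clones must be >= 1")
    pmf = law.pmf()
    return rng.choice(np.arange(1, law.max_size + 1), size=s, p=pmf)


@dataclass(frozen=True)
class GeneProfile:
    """Base germline frequency profiles for one specificity group."""

    trbv: dict = field(default_factory=lambda: dict(DEFAULT_TRBV))
    trav: dict = field(default_factory=lambda: dict(DEFAULT_TRAV))


@dataclass(frozen=True)
class GermlineModel:
    """Per-group base profiles plus the Dirichlet concentration kappa.

    Each sample's own usage profile is drawn from Dirichlet(kappa * base);
    large kappa keeps samples of one group close to the shared base.
    """

    profiles: dict = field(default_factory=lambda: {"shared": GeneProfile()})
    kappa: float = 100.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")


@dataclass(frozen=True)
class CDR3Model:
    """Amino-acid length laws per chain; flanks fixed to C...F."""

    trb_lengths: dict = field(default_factory=lambda: dict(DEFAULT_TRB_LENGTHS))
    tra_lengths: dict = field(default_factory=lambda: dict(DEFAULT_TRA_LENGTHS))


@dataclass(frozen=True)
class ClusterModel:
    """Softmax model for per-cell transcriptional cluster labels.

    A cell in a clone of size k falls in cluster c with probability
    proportional to pi_c * k^beta1 for c in the group's target set, and
    pi_c otherwise.  At k = 1 (lowly expanded) the distribution is exactly
    the baseline pi.
    """

    cluster_ids: tuple = tuple(str(i) for i in range(8))
    baseline: dict = field(default_factory=lambda: {
        "0": 0.18, "1": 0.16, "2": 0.14, "3": 0.12,
        "4": 0.12, "5": 0.10, "6": 0.10, "7": 0.08,
    })
    beta1: float = 0.8
    targets: dict = field(default_factory=lambda: {
        "acute": ("1",), "chronic": ("5",), "latent": ("2",),
    })

    def __post_init__(self) -> None:
        if not self.cluster_ids:
            raise ValidationError("cluster list must be non-empty")
        missing = set(self.cluster_ids) - set(self.baseline)
        if missing:
            raise ValidationError(f"baseline missing clusters: {sorted(missing)}")

    def target_set(self, group_label: str) -> tuple:
        return tuple(self.targets.get(group_label, ()))

    def probabilities(self, clone_size: int, group_label: str) -> np.ndarray:
        targets = set(self.target_set(group_label))
        w = np.array([
            self.baseline[c] * (clone_size ** self.beta1 if c in targets else 1.0)
            for c in self.cluster_ids
        ])
        return w / w.sum()

    def target_probability(self, clone_size: int, group_label: str) -> float:
        targets = set(self.target_set(group_label))
        p = self.probabilities(clone_size, group_label)
        return float(sum(p[i] for i, c in enumerate(self.cluster_ids) if c in targets))


def implied_target_log_or(
    sizes: np.ndarray, model: ClusterModel, group_label: str
) -> float:
    """Exact model-implied cell-level log odds ratio (expanded vs lowly
    expanded) of membership in the group's target-cluster set, given the
    planted clone sizes."""
    sizes = np.asarray(sizes)
    low = sizes[sizes == 1]
    exp = sizes[sizes >= 2]
    if low.size == 0 or exp.size == 0:
        raise ValidationError("need both singleton and expanded clones")
    p_low = model.target_probability(1, group_label)
    if not 0 < p_low < 1:
        raise ValidationError(
            f"target-cluster set for group {group_label!r} is empty or saturating"
        )
    exp_cells = exp.sum()
    p_exp = float(sum(k * model.target_probability(int(k), group_label) for k in exp) / exp_cells)
    return math.log(p_exp / (1 - p_exp)) - math.log(p_low / (1 - p_low))


def beta1_for_target_log_or(
    sizes: np.ndarray,
    model: ClusterModel,
    group_label: str,
    target_log_or: float,
) -> float:
    """Solve for beta1 so the model-implied target log-OR equals the request."""
    def f(b: float) -> float:
        m = ClusterModel(
            cluster_ids=model.cluster_ids, baseline=model.baseline,
            beta1=b, targets=model.targets,
        )
        return implied_target_log_or(sizes, m, group_label) - target_log_or

    return float(brentq(f, 0.0, 10.0, xtol=1e-10))


@dataclass(frozen=True)
class ContaminationModel:
    """Per-cell corruption rates that make cells fail the chain-count QC."""

    p_drop_tra: float = 0.04
    p_drop_trb: float = 0.03
    p_extra_chain: float = 0.03

    def __post_init__(self) -> None:
        for p in (self.p_drop_tra, self.p_drop_trb, self.p_extra_chain):
            if not 0 <= p <= 1:
                raise ValidationError("contamination probabilities must be in [0, 1]")

    @property
    def any_contamination(self) -> bool:
        return max(self.p_drop_tra, self.p_drop_trb, self.p_extra_chain) > 0


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group_label: str
    n_clones: int = 300
    size_law: SizeLaw = SizeLaw()
    profile: str | None = None  # germline profile key; defaults below

    def profile_key(self, germline: GermlineModel) -> str:
        if self.profile is not None:
            return self.profile
        if self.group_label in germline.profiles:
            return self.group_label
        if len(germline.profiles) == 1:
            return next(iter(germline.profiles))
        raise ValidationError(
            f"sample {self.sample_id}: no germline profile for group "
            f"{self.group_label!r} and no unique default"
        )


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    samples: tuple = ()
    germline: GermlineModel = GermlineModel()
    cdr3: CDR3Model = CDR3Model()
    clusters: ClusterModel = ClusterModel()
    contamination: ContaminationModel = ContaminationModel()
    public_clone_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.public_clone_rate <= 1:
            raise ValidationError("public_clone_rate must be in [0, 1]")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample_ids in config")


# Size-law presets used throughout the docs: an acute-like resolved
# infection (steep law, many singletons) versus chronic-/latent-like
# ongoing antigen exposure (shallow law, heavy expansion).  The names are
# documentation shorthand, not a biological claim.
ACUTE_LIKE_ALPHA = 3.0
CHRONIC_LIKE_ALPHA = 1.8


def default_cohort_config(seed: int = 0, n_clones: int = 300) -> GeneratorConfig:
    """The 6-mouse, 3-condition, 2-replicate study layout with one shared
    germline profile (all cells share one antigen specificity)."""
    samples = []
    for group, alpha in (("acute", ACUTE_LIKE_ALPHA),
                         ("chronic", CHRONIC_LIKE_ALPHA),
                         ("latent", CHRONIC_LIKE_ALPHA)):
        for rep in (1, 2):
            samples.append(SampleSpec(
                sample_id=f"{group}{rep}", group_label=group,
                n_clones=n_clones,
                size_law=SizeLaw("powerlaw", alpha, 1000),
            ))
    return GeneratorConfig(seed=seed, samples=tuple(samples))


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    # fixed-offset substreams: regenerating one sample never disturbs others
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _random_cdr3(lengths: dict, rng: np.random.Generator) -> tuple[str, str]:
    lens = sorted(lengths)
    probs = np.array([lengths[l] for l in lens], dtype=float)
    L = int(rng.choice(lens, p=probs / probs.sum()))
    middle = rng.choice(_NONSTOP_CODONS, size=max(L - 2, 0))
    codons = [str(rng.choice(_CYS_CODONS))] + [str(c) for c in middle] + [str(rng.choice(_PHE_CODONS))]
    nt = "".join(codons)
    aa = "".join(_CODON_TO_AA[c] for c in codons)
    return nt, aa


@dataclass
class SampleTruth:
    """Planted per-sample clone table plus derived planted quantities."""

    sample_id: str
    group_label: str
    clones: pd.DataFrame  # clone_id, cdr3b_nt, cdr3a_nt, cdr3b_aa, cdr3a_aa, trbv, trav, size, is_public_copy
    beta1: float
    implied_log_or: float | None
    perturbed_trbv: dict
    perturbed_trav: dict


def _plant_clones(
    spec: SampleSpec,
    config: GeneratorConfig,
    rng: np.random.Generator,
    used_keys: set[str],
) -> SampleTruth:
    sizes = sample_clone_sizes(spec.n_clones, spec.size_law, rng)
    profile = config.germline.profiles[spec.profile_key(config.germline)]
    trbv_genes = sorted(profile.trbv)
    trav_genes = sorted(profile.trav)
    base_b = np.array([profile.trbv[g] for g in trbv_genes], dtype=float)
    base_a = np.array([profile.trav[g] for g in trav_genes], dtype=float)
    pert_b = rng.dirichlet(config.germline.kappa * base_b / base_b.sum())
    pert_a = rng.dirichlet(config.germline.kappa * base_a / base_a.sum())

    rows = []
    for i, size in enumerate(sizes):
        while True:  # enforce cohort-wide clonotype-key uniqueness
            b_nt, b_aa = _random_cdr3(config.cdr3.trb_lengths, rng)
            a_nt, a_aa = _random_cdr3(config.cdr3.tra_lengths, rng)
            key = f"{b_nt}_{a_nt}"
            if key not in used_keys:
                used_keys.add(key)
                break
        rows.append({
            "clone_id": key,
            "cdr3b_nt": b_nt, "cdr3a_nt": a_nt,
            "cdr3b_aa": b_aa, "cdr3a_aa": a_aa,
            "trbv": str(rng.choice(trbv_genes, p=pert_b)),
            "trav": str(rng.choice(trav_genes, p=pert_a)),
            "trbj": str(rng.choice(TRBJ_GENES)),
            "traj": str(rng.choice(TRAJ_GENES)),
            "size": int(size),
            "is_public_copy": False,
        })
    clones = pd.DataFrame(rows)
    try:
        log_or = implied_target_log_or(sizes, config.clusters, spec.group_label)
    except ValidationError:
        log_or = None
    return SampleTruth(
        sample_id=spec.sample_id, group_label=spec.group_label,
        clones=clones, beta1=config.clusters.beta1, implied_log_or=log_or,
        perturbed_trbv=dict(zip(trbv_genes, pert_b.tolist())),
        perturbed_trav=dict(zip(trav_genes, pert_a.tolist())),
    )


TENX_OUT_COLUMNS = (
    "barcode", "is_cell", "contig_id", "high_confidence", "chain",
    "v_gene", "d_gene", "j_gene", "productive", "cdr3", "cdr3_nt", "umis",
)


def _emit_cells(
    truth: SampleTruth,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a planted clone table into contig and annotation rows."""
    cont = config.contamination
    contig_rows: list[dict] = []
    annot_rows: list[dict] = []
    cell_counter = 0
    for clone in truth.clones.itertuples(index=False):
        p_cluster = config.clusters.probabilities(clone.size, truth.group_label)
        labels = rng.choice(config.clusters.cluster_ids, size=clone.size, p=p_cluster)
        for label in labels:
            cell_counter += 1
            barcode = f"{truth.sample_id}_BC{cell_counter:06d}-1"
            drop_tra = rng.random() < cont.p_drop_tra
            drop_trb = rng.random() < cont.p_drop_trb
            extra = rng.random() < cont.p_extra_chain
            chains = []
            if not drop_tra:
                chains.append(("TRA", clone.trav, clone.traj, clone.cdr3a_nt, clone.cdr3a_aa))
            if not drop_trb:
                chains.append(("TRB", clone.trbv, clone.trbj, clone.cdr3b_nt, clone.cdr3b_aa))
            if extra:  # doublet-style second TRB from a random sequence
                nt, aa = _random_cdr3(config.cdr3.trb_lengths, rng)
                chains.append(("TRB", str(rng.choice(sorted(DEFAULT_TRBV))),
                               str(rng.choice(TRBJ_GENES)), nt, aa))
            for k, (locus, v, j, nt, aa) in enumerate(chains, start=1):
                contig_rows.append({
                    "barcode": barcode, "is_cell": "True",
                    "contig_id": f"{barcode}_contig_{k}",
                    "high_confidence": "True", "chain": locus,
                    "v_gene": v, "d_gene": "TRBD1" if locus == "TRB" else "",
                    "j_gene": j, "productive": "True",
                    "cdr3": aa, "cdr3_nt": nt,
                    "umis": int(rng.integers(1, 50)),
                })
            annot_rows.append({
                "barcode": barcode, "sample_id": truth.sample_id,
                "group_label": truth.group_label, "cluster_id": str(label),
            })
    contigs = pd.DataFrame(contig_rows, columns=list(TENX_OUT_COLUMNS))
    annotations = pd.DataFrame(
        annot_rows, columns=["barcode", "sample_id", "group_label", "cluster_id"]
    )
    return contigs, annotations


def generate_repertoire(
    config: GeneratorConfig, sample_index: int
) -> tuple[pd.DataFrame, pd.DataFrame, SampleTruth]:
    """Generate one sample (no cross-sample public clones).

    Returns (contig table in the 10x dialect, annotation table, ground
    truth).  Deterministic under a fixed config seed.
    """
    spec = config.samples[sample_index]
    rng = _sample_rng(config.seed, sample_index)
    truth = _plant_clones(spec, config, rng, used_keys=set())
    contigs, annotations = _emit_cells(truth, config, rng)
    return contigs, annotations, truth


@dataclass
class CohortData:
    """In-memory result of cohort generation."""

    contigs: dict  # sample_id -> contig DataFrame (10x dialect)
    annotations: pd.DataFrame  # pooled across samples
    truths: dict  # sample_id -> SampleTruth
    manifest: dict


def generate_cohort(config: GeneratorConfig, out_dir=None) -> CohortData:
    """Generate a full cohort, optionally writing it to *out_dir*.

    Writes per-sample ``<sample_id>_filtered_contig_annotations.csv``, a
    pooled ``annotations.tsv``, and ``manifest.json`` with every planted
    parameter.  Public clones are copied across samples at
    ``public_clone_rate`` (always as singletons in the destination) and
    recorded in the manifest.
    """
    if not config.samples:
        raise ValidationError("config must declare at least one sample")
    used_keys: set[str] = set()
    truths: dict[str, SampleTruth] = {}
    for idx, spec in enumerate(config.samples):
        rng = _sample_rng(config.seed, idx)
        truths[spec.sample_id] = _plant_clones(spec, config, rng, used_keys)

    planted_public: list[dict] = []
    sample_ids = [s.sample_id for s in config.samples]
    if config.public_clone_rate > 0 and len(sample_ids) > 1:
        pub_rng = _sample_rng(config.seed, 1_000_003)
        for sid in sample_ids:
            truth = truths[sid]
            for clone in truth.clones.itertuples(index=False):
                if clone.is_public_copy or pub_rng.random() >= config.public_clone_rate:
                    continue
                others = [s for s in sample_ids if s != sid]
                dest = str(pub_rng.choice(others))
                dest_clones = truths[dest].clones
                if clone.clone_id in set(dest_clones["clone_id"]):
                    continue
                copy = {**clone._asdict(), "size": 1, "is_public_copy": True}
                truths[dest].clones = pd.concat(
                    [dest_clones, pd.DataFrame([copy])], ignore_index=True
                )
                planted_public.append(
                    {"clone_id": clone.clone_id, "source": sid, "dest": dest}
                )

    contigs: dict[str, pd.DataFrame] = {}
    annot_frames: list[pd.DataFrame] = []
    for idx, spec in enumerate(config.samples):
        rng = _sample_rng(config.seed, 500_000 + idx)
        c, a = _emit_cells(truths[spec.sample_id], config, rng)
        contigs[spec.sample_id] = c
        annot_frames.append(a)
    annotations = pd.concat(annot_frames, ignore_index=True)

    manifest = {
        "seed": config.seed,
        "public_clone_rate": config.public_clone_rate,
        "planted_public_clones": planted_public,
        "beta1": config.clusters.beta1,
        "cluster_targets": {k: list(v) for k, v in config.clusters.targets.items()},
        "contamination": asdict(config.contamination),
        "germline_kappa": config.germline.kappa,
        "samples": {
            sid: {
                "group_label": t.group_label,
                "n_clones": int(len(t.clones)),
                "n_cells": int(t.clones["size"].sum()),
                "implied_target_log_or": t.implied_log_or,
                "clone_sizes": t.clones["size"].tolist(),
            }
            for sid, t in truths.items()
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, df in contigs.items():
            df.to_csv(out / f"{sid}_filtered_contig_annotations.csv", index=False)
        annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        for sid, t in truths.items():
            t.clones.to_csv(out / f"{sid}_truth_clones.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return CohortData(contigs=contigs, annotations=annotations,
                      truths=truths, manifest=manifest)
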