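"""Synthetic cohort, expression, gene-set and patch-bag generators.

Emulates the data structure of a real-world recurrent/metastatic HNSCC
cohort treated with pembrolizumab with or without chemotherapy: two
treatment arms (106 / 124 patients by default), right-censored
progression-free survival over a 24-month follow-up window, the usual
clinical covariates (age, sex, biopsy site, PD-L1 CPS category, HPV,
tumor purity, smoking, ECOG, sequencing batch), a negative-binomial
bulk RNA-seq count matrix with a planted prognostic gene block and six
correlated TLS-like gene sets, and per-patient bags of whole-slide-image
patch embeddings with planted informative patches.

Every generator is bit-reproducible given its config (the seed lives in
the config).  Ground truth (latent risk, planted gene indices,
informative patch indices) is exported alongside the data and never
mixed into analysis inputs.

The latent patient risk decomposes as

    latent_risk = covariate term + risk_mol + risk_img

where ``risk_mol`` (a molecular latent factor minus a protective TLS
factor contribution) drives the expression of the planted prognostic
genes and ``risk_img`` drives the composition of the patch bags.  The
two modality-visible components are independent, so transcriptome and
imaging carry complementary prognostic information — the structure the
late-fusion analyses assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from scipy.optimize import brentq

__all__ = [
    "CohortConfig",
    "ExpressionConfig",
    "BagConfig",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "PatchBag",
    "PatchBagSet",
    "generate_cohort",
    "generate_expression",
    "generate_gene_sets",
    "generate_patch_bags",
]

ARMS = ("Pembro", "PembroChemo")
PATCH_GRID_PX = 224


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 106 Pembro / 124 Pembro+Chemo
    patients followed for up to 24 months.  ``censoring_rate`` is the
    target overall censored fraction (administrative cap included); the
    rate of the independent exponential censoring process is calibrated
    to it by root-finding.
    """

    n_pembro: int = 106
    n_chemo: int = 124
    censoring_rate: float = 0.25
    followup_cap_months: float = 24.0
    baseline_hazard: float = np.log(2) / 6.0  # events/month; median ~6 mo at risk 0
    covariate_effect_logHR: float = 0.1
    mol_risk_sd: float = 0.9       # sd of the molecular-visible latent component
    img_risk_sd: float = 1.4       # sd of the imaging-visible latent component
    tls_effect_logHR: float = -0.5  # protective TLS factor effect (part of risk_mol)
    weibull_shape: float = 1.0     # 1.0 = exponential PFS
    frac_cps_unknown: float = 0.51
    frac_hpv_known: float = 0.24   # fraction with lab-confirmed HPV status
    frac_ecog_unknown: float = 0.57
    frac_smoking_unknown: float = 0.11
    n_batches: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_pembro + self.n_chemo < 2:
            raise ValueError("cohort must contain at least 2 patients")
        if not 0 < self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in (0, 1)")
        if self.followup_cap_months <= 0:
            raise ValueError("followup_cap_months must be > 0")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline_hazard and weibull_shape must be > 0")


@dataclass
class ExpressionConfig:
    """Parameters of the negative-binomial bulk RNA-seq emulator."""

    n_genes: int = 20000
    n_prognostic: int = 150
    prognostic_logHR: float = 0.6  # per-unit-risk log-mean shift of prognostic genes
    n_tls_genes: int = 240         # size of the TLS-loaded gene block
    tls_factor_loading: float = 0.8
    dispersion: float = 0.15       # NB: var = mu + dispersion * mu^2
    library_size_sd: float = 0.15  # lognormal sd of per-sample depth factor
    batch_sd: float = 0.3          # sd of per-gene per-batch log offsets
    hpv_cdkn2a_shift: float = 1.5  # log-mean CDKN2A shift in HPV-positive tumors
    seed: int = 0

    def validate(self) -> None:
        if self.n_prognostic > self.n_genes:
            raise ValueError("n_prognostic cannot exceed n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_prognostic + self.n_tls_genes + 1 > self.n_genes:
            raise ValueError("prognostic + TLS blocks exceed n_genes")


@dataclass
class BagConfig:
    """Parameters of the patch-embedding bag generator.

    Patches live on a 224-pixel grid (non-overlapping 224x224 tiles).
    A latent-risk-dependent fraction of patches is shifted by
    +shift ("TLS-like", enriched in low-risk patients) or -shift
    ("necrosis-like", enriched in high-risk patients) along a fixed
    random direction of norm ``informative_shift``.
    """

    patches_min: int = 40
    patches_max: int = 100
    embed_dim: int = 16
    informative_fraction: float = 0.35
    informative_shift: float = 3.0
    marker_shift: float = 2.0      # shared salience axis of informative patches
    risk_slope: float = 2.5        # steepness of the risk -> composition link
    patch_grid_px: int = PATCH_GRID_PX
    seed: int = 0

    def validate(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if not 0 <= self.informative_fraction <= 1:
            raise ValueError("informative_fraction must lie in [0, 1]")
        if self.patches_min < 1 or self.patches_max < self.patches_min:
            raise ValueError("invalid patches_per_bag range")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with an explicit state flag."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    state: str = "counts"  # "counts" or "normalized"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSet:
    name: str
    members: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.sets:
                fh.write("\t".join([s.name, s.description or "na", *s.members]) + "\n")

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets.append(GeneSet(parts[0], parts[2:], description=parts[1]))
        return cls(sets)


@dataclass
class PatchBag:
    """One patient's slide as an N x D embedding matrix plus coordinates."""

    patient_id: str
    embeddings: np.ndarray  # N x D float32
    coords: np.ndarray      # N x 2 int (pixel origins, multiples of 224)

    def __post_init__(self) -> None:
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError("embeddings must be a non-empty N x D matrix")
        if self.coords.shape != (self.embeddings.shape[0], 2):
            raise ValueError("coords must be N x 2")
        if np.any(self.coords < 0) or np.any(self.coords % PATCH_GRID_PX != 0):
            raise ValueError("coords must be non-negative multiples of 224")
        uniq = {tuple(c) for c in self.coords.tolist()}
        if len(uniq) != self.coords.shape[0]:
            raise ValueError("coords must be unique within a bag")

    @property
    def n_patches(self) -> int:
        return self.embeddings.shape[0]


@dataclass
class PatchBagSet:
    bags: dict[str, PatchBag]
    informative_idx: dict[str, np.ndarray] = field(default_factory=dict)
    informative_kind: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, pid: str) -> PatchBag:
        return self.bags[pid]

    def __len__(self) -> int:
        return len(self.bags)

    def write_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for pid, bag in self.bags.items():
                g = fh.create_group(pid)
                g.create_dataset("embeddings", data=bag.embeddings.astype(np.float32))
                g.create_dataset("coords", data=bag.coords.astype(np.int64))

    @classmethod
    def read_h5(cls, path) -> "PatchBagSet":
        import h5py

        bags = {}
        with h5py.File(path, "r") as fh:
            for pid in fh:
                bags[pid] = PatchBag(
                    pid,
                    np.asarray(fh[pid]["embeddings"], dtype=np.float32),
                    np.asarray(fh[pid]["coords"], dtype=np.int64),
                )
        return cls(bags)


# --------------------------------------------------------------------------
# cohort

def _censoring_rate_given_rho(rho, lam, cap):
    """E[fraction censored] with C = min(Exp(rho), cap), T = Exp(lam)."""
    lam = np.asarray(lam)
    total = rho + lam
    p_cens = np.where(
        total > 0,
        rho / np.where(total > 0, total, 1.0) * (1 - np.exp(-total * cap))
        + np.exp(-total * cap),
        1.0,
    )
    return float(np.mean(p_cens))


def _calibrate_censoring(target, lam, cap):
    """Root-find the exponential censoring rate hitting the target fraction.

    The administrative cap alone already censors E[exp(-lam*cap)]; if the
    target is below that floor the independent process is switched off.
    """
    floor = _censoring_rate_given_rho(0.0, lam, cap)
    if target <= floor:
        return 0.0
    f = lambda r: _censoring_rate_given_rho(r, lam, cap) - target
    hi = 1.0
    while f(hi) < 0 and hi < 1e6:
        hi *= 10
    return brentq(f, 1e-12, hi, xtol=1e-10)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate the clinical table, latent risks and right-censored PFS.

    Returns one row per patient.  Observable columns mimic the clinical
    CSV; ``latent_risk``, ``risk_mol``, ``risk_img``, ``tls_factor`` and
    the latent (pre-masking) covariates are ground truth and must be
    dropped before any analysis that claims to be blinded.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pembro + config.n_chemo
    if config.n_pembro == 0 or config.n_chemo == 0:
        raise ValueError("both treatment arms must be non-empty")

    arm = np.array([ARMS[0]] * config.n_pembro + [ARMS[1]] * config.n_chemo)
    patient_id = np.array([f"PT{i:04d}" for i in range(n)])

    age = np.clip(rng.normal(63, 9, n), 25, 92).round(0)
    sex = np.where(rng.random(n) < 0.84, "M", "F")
    biopsy_site = rng.choice(
        ["BronchusLungs", "HeadFaceMouthNeck", "Other"], size=n, p=[0.22, 0.45, 0.33]
    )
    tumor_purity = np.clip(rng.normal(60, 20, n), 5, 95).round(0)
    smoking_latent = np.where(rng.random(n) < 0.69, "ever", "never")
    ecog_latent = np.where(rng.random(n) < 0.33, "0", "1")
    hpv_latent = np.where(rng.random(n) < 0.54, "positive", "negative")
    cps_value = np.exp(rng.normal(1.6, 1.3, n))  # latent CPS, lognormal
    batch = rng.integers(0, config.n_batches, n)

    # latent risk components
    u_tls = rng.normal(0, 1, n)
    u_mol = rng.normal(0, 1, n)
    u_img = rng.normal(0, 1, n)
    age_std = (age - age.mean()) / max(age.std(), 1e-9)
    cov_term = config.covariate_effect_logHR * (
        age_std + (sex == "M") * 0.5 + (ecog_latent == "1") * 0.5
    )
    risk_mol = config.mol_risk_sd * u_mol + config.tls_effect_logHR * u_tls
    risk_img = config.img_risk_sd * u_img
    latent_risk = cov_term + risk_mol + risk_img

    lam = config.baseline_hazard * np.exp(latent_risk)
    # Weibull with shape k: T = (E / lam)^(1/k), E ~ Exp(1); k=1 -> exponential
    e = rng.exponential(1.0, n)
    t_event = (e / lam) ** (1.0 / config.weibull_shape)

    rho = _calibrate_censoring(config.censoring_rate, lam, config.followup_cap_months)
    c_indep = rng.exponential(1.0 / rho, n) if rho > 0 else np.full(n, np.inf)
    c_time = np.minimum(c_indep, config.followup_cap_months)
    event = (t_event <= c_time).astype(int)
    pfs = np.where(event == 1, t_event, c_time)
    pfs = np.maximum(pfs, 1e-3)  # times must be strictly positive

    cps_category = np.where(
        cps_value < 1, "negative", np.where(cps_value < 20, "low", "high")
    )
    cps_category = np.where(
        rng.random(n) < config.frac_cps_unknown, "unknown", cps_category
    )
    hpv = np.where(rng.random(n) < config.frac_hpv_known, hpv_latent, "unknown")
    ecog = np.where(rng.random(n) < config.frac_ecog_unknown, "unknown", ecog_latent)
    smoking = np.where(
        rng.random(n) < config.frac_smoking_unknown, "unknown", smoking_latent
    )

    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "arm": arm,
            "pfs_months": pfs,
            "event": event,
            "age": age,
            "sex": sex,
            "biopsy_site": biopsy_site,
            "cps_category": cps_category,
            "hpv": hpv,
            "tumor_purity": tumor_purity,
            "smoking": smoking,
            "ecog": ecog,
            "batch": [f"B{b}" for b in batch],
            # ---- ground truth (never analysis input) ----
            "latent_risk": latent_risk,
            "risk_mol": risk_mol,
            "risk_img": risk_img,
            "tls_factor": u_tls,
            "hpv_latent": hpv_latent,
            "cps_value": cps_value,
        }
    ).set_index("patient_id", drop=False)


GROUND_TRUTH_COLS = [
    "latent_risk",
    "risk_mol",
    "risk_img",
    "tls_factor",
    "hpv_latent",
    "cps_value",
]


def observable_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop the ground-truth columns (the analysis-facing clinical table)."""
    return cohort.drop(columns=[c for c in GROUND_TRUTH_COLS if c in cohort])


# --------------------------------------------------------------------------
# expression

def _gene_names(config: ExpressionConfig) -> list[str]:
    names = [f"G{i:05d}" for i in range(config.n_genes)]
    # CDKN2A is the HPV proxy gene; it replaces the last null gene's name
    names[-1] = "CDKN2A"
    return names


def generate_expression(
    cohort: pd.DataFrame, config: ExpressionConfig
) -> tuple[ExpressionMatrix, dict]:
    """Negative-binomial counts with planted prognostic and TLS structure.

    Layout: genes 0..n_prognostic-1 are prognostic (log-mean shifted by
    risk_mol x prognostic_logHR, alternating sign), the next n_tls_genes
    load on the TLS factor, the final gene is CDKN2A whose mean tracks
    latent HPV status.  Batch adds a per-gene, per-batch log offset.

    Returns the counts matrix and a ground-truth dict (planted indices,
    per-gene signs/loadings).
    """
    config.validate()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    g = config.n_genes
    names = _gene_names(config)

    base = rng.normal(4.0, 1.5, g)  # natural-log mean counts
    log_mu = np.tile(base[:, None], (1, n))

    prog_idx = np.arange(config.n_prognostic)
    signs = np.where(np.arange(config.n_prognostic) % 2 == 0, 1.0, -1.0)
    risk_mol = cohort["risk_mol"].to_numpy()
    log_mu[prog_idx] += (
        signs[:, None] * config.prognostic_logHR * risk_mol[None, :]
    )

    tls_idx = np.arange(config.n_prognostic, config.n_prognostic + config.n_tls_genes)
    tls_load = rng.uniform(0.5, 1.0, config.n_tls_genes) * config.tls_factor_loading
    u_tls = cohort["tls_factor"].to_numpy()
    log_mu[tls_idx] += tls_load[:, None] * u_tls[None, :]

    cdkn2a_idx = g - 1
    hpv_pos = (cohort["hpv_latent"] == "positive").to_numpy()
    log_mu[cdkn2a_idx] += config.hpv_cdkn2a_shift * hpv_pos

    batches = cohort["batch"].to_numpy()
    for b in np.unique(batches):
        offset = rng.normal(0, config.batch_sd, g)
        log_mu[:, batches == b] += offset[:, None]

    lib = rng.normal(0, config.library_size_sd, n)
    log_mu += lib[None, :]

    mu = np.exp(np.clip(log_mu, -10, 14))
    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(np.int64)

    mat = ExpressionMatrix(
        values=pd.DataFrame(counts, index=names, columns=cohort.index),
        state="counts",
    )
    truth = {
        "prognostic_genes": [names[i] for i in prog_idx],
        "prognostic_signs": signs.tolist(),
        "tls_genes": [names[i] for i in tls_idx],
        "tls_loadings": tls_load.tolist(),
        "cdkn2a_gene": "CDKN2A",
    }
    return mat, truth


TLS_SET_NAMES = [
    "tls_chemokine",
    "tls_tfh_cell",
    "tls_th1_bcell",
    "tls_bcell",
    "tls_plasma_cell",
    "tls_imprint",
]


def generate_gene_sets(
    expr_config: ExpressionConfig,
    set_size_range: tuple[int, int] = (20, 50),
    n_decoys: int = 0,
    decoy_size: int = 30,
    seed: int | None = None,
) -> GeneSetCollection:
    """Six TLS-like gene sets drawn from the TLS-loaded block, plus decoys.

    Decoy sets are drawn from the null gene block and carry no signal.
    """
    expr_config.validate()
    if n_decoys > 0 and decoy_size <= 0:
        raise ValueError("decoy set size must be positive")
    rng = np.random.default_rng(expr_config.seed if seed is None else seed)
    names = _gene_names(expr_config)
    lo, hi = set_size_range
    if hi > expr_config.n_tls_genes:
        raise ValueError("requested set size exceeds available TLS-loaded genes")
    tls_pool = names[
        expr_config.n_prognostic : expr_config.n_prognostic + expr_config.n_tls_genes
    ]
    sets = []
    for name in TLS_SET_NAMES:
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(tls_pool, size=size, replace=False))
        sets.append(GeneSet(name, members, description="synthetic TLS-like set"))
    null_pool = names[expr_config.n_prognostic + expr_config.n_tls_genes : -1]
    for d in range(n_decoys):
        members = list(rng.choice(null_pool, size=decoy_size, replace=False))
        sets.append(GeneSet(f"decoy_{d}", members, description="random decoy set"))
    return GeneSetCollection(sets)


# --------------------------------------------------------------------------
# patch bags

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_patch_bags(cohort: pd.DataFrame, config: BagConfig) -> PatchBagSet:
    """One bag of patch embeddings per patient.

    Background patches are standard normal; "TLS-like" patches add
    +shift_vec and "necrosis-like" patches add -shift_vec along a fixed
    axis, with the two counts binomially drawn at rates tilted by the
    patient's imaging risk component (low risk -> TLS-enriched, high
    risk -> necrosis-enriched).  Both kinds additionally share a
    "salience" offset along an orthogonal marker axis — informative
    tissue (lymphoid aggregates, necrosis) is visually distinct from
    background stroma in a common way before it differs by kind.
    Coordinates are unique multiples of 224.
    """
    config.validate()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed)
    d1 = rng.normal(0, 1, config.embed_dim)
    d1 /= np.linalg.norm(d1)
    d2 = rng.normal(0, 1, config.embed_dim)
    d2 -= (d2 @ d1) * d1
    d2 /= np.linalg.norm(d2)
    shift_vec = config.informative_shift * d1
    marker_vec = config.marker_shift * d2

    risk_img = cohort["risk_img"].to_numpy()
    r_std = (risk_img - risk_img.mean()) / max(risk_img.std(), 1e-9)

    bags: dict[str, PatchBag] = {}
    info_idx: dict[str, np.ndarray] = {}
    info_kind: dict[str, np.ndarray] = {}
    for pid, r in zip(cohort.index, r_std):
        n_patch = int(rng.integers(config.patches_min, config.patches_max + 1))
        p_tls = config.informative_fraction * _sigmoid(-config.risk_slope * r)
        p_nec = config.informative_fraction * _sigmoid(config.risk_slope * r)
        n_tls = rng.binomial(n_patch, p_tls)
        n_nec = rng.binomial(n_patch - n_tls, p_nec) if n_patch > n_tls else 0

        emb = rng.normal(0, 1, (n_patch, config.embed_dim))
        order = rng.permutation(n_patch)
        tls_ids = order[:n_tls]
        nec_ids = order[n_tls : n_tls + n_nec]
        emb[tls_ids] += shift_vec + marker_vec
        emb[nec_ids] += -shift_vec + marker_vec

        side = int(np.ceil(np.sqrt(n_patch))) * 2
        cells = rng.choice(side * side, size=n_patch, replace=False)
        coords = np.stack([cells % side, cells // side], axis=1) * config.patch_grid_px

        bags[pid] = PatchBag(pid, emb.astype(np.float32), coords.astype(np.int64))
        idx = np.concatenate([tls_ids, nec_ids]).astype(int)
        kind = np.array(["tls"] * n_tls + ["necrosis"] * n_nec)
        info_idx[pid] = idx
        info_kind[pid] = kind
    return PatchBagSet(bags, info_idx, info_kind)


# --------------------------------------------------------------------------
# bundle I/O

def write_dataset(
    out_dir,
    cohort: pd.DataFrame,
    expr: ExpressionMatrix | None = None,
    gene_sets: GeneSetCollection | None = None,
    bags: PatchBagSet | None = None,
    truth: dict | None = None,
) -> None:
    """Write the standard artifact bundle (clinical CSV, expression TSV,
    GMT, HDF5 bags, ground-truth JSON) to ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    observable_cohort(cohort).to_csv(out / "clinical.csv", index=False)
    gt = cohort[[c for c in GROUND_TRUTH_COLS if c in cohort]].copy()
    payload = {"latent": {c: gt[c].tolist() for c in gt.columns},
               "patient_id": cohort["patient_id"].tolist()}
    if truth:
        payload.update(truth)
    if bags is not None:
        payload["informative_patches"] = {
            pid: idx.tolist() for pid, idx in bags.informative_idx.items()
        }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh)
    if expr is not None:
        expr.values.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    if gene_sets is not None:
        gene_sets.write_gmt(out / "gene_sets.gmt")
    if bags is not None:
        bags.write_h5(out / "bags.h5")
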