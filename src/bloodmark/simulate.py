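"""Synthetic cohort generator.

Emulates a small three-group blood RNA-seq study (healthy controls,
methamphetamine dependents without psychosis [MA], and methamphetamine-
associated psychosis [MAP], n=10 each by default) with the statistical
structure the downstream analyses assume:

* negative-binomial counts around library-size-scaled expected expression;
* planted co-expression modules, each driven by a single per-subject latent
  factor with gene-wise loadings;
* group effects expressed as log2-scale shifts of selected module factors;
* phenotypes (brain-structure volumes in mm^3, psychometric totals,
  substance-use counts) linearly coupled to module factors plus Gaussian
  noise;
* a designated confounder module whose factor drives the substance-use
  covariates (so confounder-module exclusion is testable downstream);
* an external evidence database enriched in planted-module genes.

Everything planted is recorded in a :class:`SyntheticTruth` ledger so that
recovery can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "MA", "MAP")

#: brain regions with rough adult volume baselines (mm^3) and noise scale
BRAIN_REGIONS = {
    "hippocampus_L": (4200.0, 350.0),
    "hippocampus_R": (4300.0, 350.0),
    "accumbens_L": (600.0, 70.0),
    "accumbens_R": (580.0, 70.0),
    "caudate_L": (3800.0, 300.0),
    "caudate_R": (3900.0, 300.0),
    "putamen_L": (5300.0, 400.0),
    "putamen_R": (5200.0, 400.0),
    "ventralDC_L": (4200.0, 300.0),
    "ventralDC_R": (4150.0, 300.0),
    "CC_anterior": (900.0, 90.0),
    "CC_posterior": (1000.0, 90.0),
}

#: psychometric instruments: baseline total and between-subject sd
PSYCHOMETRICS = {
    "EPQRS_psychoticism": (8.0, 3.0),
    "EPQRS_extraversion": (14.0, 4.0),
    "EPQRS_neuroticism": (12.0, 4.0),
    "BDI_total": (10.0, 6.0),
    "K10_total": (20.0, 6.0),
    "BIS_total": (20.0, 4.0),
    "BAS_total": (38.0, 5.0),
    "LEQ_total": (9.0, 3.0),
}

SUBSTANCE_USE = ("nicotine_use", "cannabis_use", "alcohol_use")

EVIDENCE_TYPES = ("blood_expression", "brain_expression", "genetic")
DISEASES = ("psychosis", "SCZ", "depression_stress", "neurocognitive")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults give a desk-scale cohort: 2000 genes, 8 planted modules of 100
    genes each, 3 groups of 10 subjects. ``group_effects`` maps a module
    index to per-group latent-factor mean shifts on the log2 scale; genes
    with loading ~1 therefore shift by roughly that many log2 units.
    """

    n_genes: int = 2000
    n_per_group: int = 10
    groups: tuple[str, ...] = GROUPS
    module_sizes: tuple[int, ...] = (100,) * 8
    loading_mean: float = 1.0
    loading_sd: float = 0.2
    group_effects: dict[int, dict[str, float]] | None = None
    nb_dispersion: float = 0.1
    lib_size_mean: float = 2.0e6
    lib_size_cv: float = 0.1
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    phenotype_couplings: dict[str, tuple[int, float, float]] | None = None
    #: -1 selects the last module automatically; None disables the confounder
    confounder_module: int | None = -1
    confounder_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "nicotine_use": 6.0,
            "cannabis_use": 4.0,
            "alcohol_use": 3.0,
        }
    )
    evidence_enrichment: dict[int, float] | None = None
    evidence_max_records: int = 3
    background_evidence_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        n_mod = self.n_modules
        if self.group_effects is None:
            defaults = {0: {"MAP": -1.0}, 1: {"MAP": 1.0, "MA": 0.4}, 2: {"MA": 0.8}}
            self.group_effects = {m: v for m, v in defaults.items() if m < n_mod}
        if self.phenotype_couplings is None:
            defaults = {
                "hippocampus_L": (0, 250.0, 200.0),
                "CC_anterior": (0, -90.0, 55.0),
                "K10_total": (0, -3.5, 3.0),
                "EPQRS_psychoticism": (1, 2.0, 1.8),
            }
            self.phenotype_couplings = {
                k: v for k, v in defaults.items() if v[0] < n_mod
            }
        if self.evidence_enrichment is None:
            defaults = {0: 0.5, 1: 0.5, 2: 0.1, 3: 0.1}
            self.evidence_enrichment = {m: p for m, p in defaults.items() if m < n_mod}
        if self.confounder_module == -1:
            self.confounder_module = n_mod - 1 if n_mod >= 4 else None

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_subjects(self) -> int:
        return self.n_per_group * len(self.groups)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 1:
            raise ConfigurationError("n_genes and n_per_group must be positive")
        if any(m < 2 for m in self.module_sizes):
            raise ConfigurationError("every module must have >= 2 genes")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.lib_size_mean <= 0 or self.lib_size_cv <= 0:
            raise ConfigurationError("library size parameters must be positive")
        for m, shifts in self.group_effects.items():
            if not 0 <= m < self.n_modules:
                raise ConfigurationError(f"group_effects references unknown module {m}")
            for g in shifts:
                if g not in self.groups:
                    raise ConfigurationError(f"group_effects references unknown group {g!r}")
        for trait, (m, _, _) in self.phenotype_couplings.items():
            if not 0 <= m < self.n_modules:
                raise ConfigurationError(
                    f"phenotype coupling {trait!r} references unknown module {m}"
                )
        for m, p in self.evidence_enrichment.items():
            if not 0 <= m < self.n_modules:
                raise ConfigurationError(f"evidence_enrichment references unknown module {m}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("evidence probabilities must lie in [0, 1]")
        if not 0.0 <= self.background_evidence_rate <= 1.0:
            raise ConfigurationError("background_evidence_rate must lie in [0, 1]")
        if self.confounder_module is not None and not (
            0 <= self.confounder_module < self.n_modules
        ):
            raise ConfigurationError("confounder_module out of range")

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A cohort with no group effects, no couplings and no evidence."""
        base = dict(
            group_effects={},
            phenotype_couplings={},
            confounder_slopes={},
            confounder_module=None,
            evidence_enrichment={},
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    """Ledger of everything planted by :func:`generate_cohort`."""

    gene_modules: pd.Series  # gene id -> module index, -1 for background
    loadings: pd.Series  # gene id -> factor loading (0 for background)
    module_factors: pd.DataFrame  # module x subject latent factors
    group_effects: dict[int, dict[str, float]]
    phenotype_couplings: dict[str, tuple[int, float, float]]
    confounder_module: int | None
    planted_de_genes: list[str]
    expected_log2: pd.DataFrame  # gene x subject expected log2 relative expression
    evidence_records: pd.DataFrame | None = None

    def module_genes(self, module: int) -> list[str]:
        return list(self.gene_modules.index[self.gene_modules == module])

    def to_json(self, path) -> None:
        payload = {
            "gene_modules": self.gene_modules.to_dict(),
            "loadings": self.loadings.to_dict(),
            "module_factors": self.module_factors.to_dict(),
            "group_effects": {str(k): v for k, v in self.group_effects.items()},
            "phenotype_couplings": {
                k: list(v) for k, v in self.phenotype_couplings.items()
            },
            "confounder_module": self.confounder_module,
            "planted_de_genes": self.planted_de_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate (counts, phenotypes, truth) for one cohort.

    Returns
    -------
    counts : DataFrame, genes x subjects, non-negative integers.
    phenotypes : DataFrame, one row per subject.
    truth : SyntheticTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_ids(config.n_genes)
    subjects = [
        f"S{g[:3].upper()}{i+1:02d}" for g in config.groups for i in range(config.n_per_group)
    ]
    group_of = np.repeat(list(config.groups), config.n_per_group)

    # gene -> module assignment: first sum(module_sizes) genes belong to
    # modules in order, the remainder is uncorrelated background
    module_idx = np.full(config.n_genes, -1, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module_idx[pos : pos + size] = m
        pos += size
    gene_modules = pd.Series(module_idx, index=genes, name="module")

    # latent factors: one per module per subject, standard normal plus the
    # configured per-group mean shift (log2 scale)
    factors = rng.standard_normal((config.n_modules, config.n_subjects))
    for m, shifts in config.group_effects.items():
        for g, delta in shifts.items():
            factors[m, group_of == g] += delta
    module_factors = pd.DataFrame(factors, columns=subjects)
    module_factors.index.name = "module"

    loadings = np.zeros(config.n_genes)
    in_module = module_idx >= 0
    loadings[in_module] = rng.normal(
        config.loading_mean, config.loading_sd, size=in_module.sum()
    )

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_genes)
    log2_expr = np.tile(base[:, None], (1, config.n_subjects))
    log2_expr[in_module] += loadings[in_module, None] * factors[module_idx[in_module]]

    # library sizes log-normal with the requested mean and CV
    sigma2 = np.log1p(config.lib_size_cv**2)
    lib = rng.lognormal(
        mean=np.log(config.lib_size_mean) - sigma2 / 2.0,
        sigma=np.sqrt(sigma2),
        size=config.n_subjects,
    )

    rel = np.exp2(log2_expr)
    props = rel / rel.sum(axis=0, keepdims=True)
    mu = props * lib[None, :]

    # NB(mean mu, var mu + phi mu^2) via gamma-Poisson mixture
    phi = config.nb_dispersion
    shape = 1.0 / phi
    counts = rng.poisson(rng.gamma(shape, mu * phi))

    counts_df = pd.DataFrame(counts, index=genes, columns=subjects)
    counts_df.index.name = "gene"

    phenotypes = _generate_phenotypes(config, rng, subjects, group_of, module_factors)

    planted = [
        g
        for g, m in gene_modules.items()
        if m in config.group_effects and any(v != 0 for v in config.group_effects[m].values())
    ]
    truth = SyntheticTruth(
        gene_modules=gene_modules,
        loadings=pd.Series(loadings, index=genes, name="loading"),
        module_factors=module_factors,
        group_effects=config.group_effects,
        phenotype_couplings=config.phenotype_couplings,
        confounder_module=config.confounder_module,
        planted_de_genes=planted,
        expected_log2=pd.DataFrame(log2_expr, index=genes, columns=subjects),
    )
    return counts_df, phenotypes, truth


def _generate_phenotypes(config, rng, subjects, group_of, module_factors) -> pd.DataFrame:
    n = len(subjects)
    data = {"subject_id": subjects, "group": group_of}

    def coupled(trait, baseline, noise_sd):
        values = np.full(n, baseline, dtype=float)
        if trait in config.phenotype_couplings:
            m, slope, eps = config.phenotype_couplings[trait]
            values = baseline + slope * module_factors.iloc[m].to_numpy()
            values += rng.normal(0.0, eps, size=n)
        else:
            values += rng.normal(0.0, noise_sd, size=n)
        return values

    for region, (baseline, sd) in BRAIN_REGIONS.items():
        vol = coupled(region, baseline, sd)
        data[region] = np.maximum(vol, 1.0)  # volumes strictly positive
    for instr, (baseline, sd) in PSYCHOMETRICS.items():
        data[instr] = coupled(instr, baseline, sd)
    for use in SUBSTANCE_USE:
        base_rate = 5.0 + rng.normal(0.0, 2.0, size=n)
        if config.confounder_module is not None and use in config.confounder_slopes:
            f = module_factors.iloc[config.confounder_module].to_numpy()
            base_rate = base_rate + config.confounder_slopes[use] * f
        data[use] = np.maximum(np.round(base_rate), 0).astype(int)

    df = pd.DataFrame(data)
    df = df.set_index("subject_id", drop=False)
    df.index.name = None
    return df


def generate_evidence_db(truth: SyntheticTruth, config: CohortConfig) -> pd.DataFrame:
    """Simulate an external literature-evidence table.

    One record per (gene, evidence_type, disease, source); genes in modules
    named in ``config.evidence_enrichment`` receive at least one record with
    the configured probability, everything else at
    ``config.background_evidence_rate``. Enriched-module genes lean towards
    blood-expression/psychosis records so the blood-psychosis weighting is
    exercised. Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    records = []
    for gene, module in truth.gene_modules.items():
        rate = config.evidence_enrichment.get(module, config.background_evidence_rate)
        if rate <= 0.0 or rng.random() >= rate:
            continue
        n_rec = rng.integers(1, config.evidence_max_records + 1)
        combos = set()
        for _ in range(n_rec):
            if rng.random() < 0.4:
                etype, disease = "blood_expression", "psychosis"
            else:
                etype = EVIDENCE_TYPES[rng.integers(len(EVIDENCE_TYPES))]
                disease = DISEASES[rng.integers(len(DISEASES))]
            if (etype, disease) in combos:
                continue
            combos.add((etype, disease))
            records.append(
                {
                    "gene": gene,
                    "evidence_type": etype,
                    "disease": disease,
                    "source_id": f"PMID{rng.integers(10_000_000, 40_000_000)}",
                    "meth_study": False,
                }
            )
    db = pd.DataFrame(
        records, columns=["gene", "evidence_type", "disease", "source_id", "meth_study"]
    )
    truth.evidence_records = db
    return db


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["group_effects"] = {str(k): v for k, v in d["group_effects"].items()}
    d["evidence_enrichment"] = {str(k): v for k, v in d["evidence_enrichment"].items()}
    d["phenotype_couplings"] = {k: list(v) for k, v in d["phenotype_couplings"].items()}
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "group_effects" in d:
        d["group_effects"] = {int(k): dict(v) for k, v in d["group_effects"].items()}
    if "evidence_enrichment" in d:
        d["evidence_enrichment"] = {int(k): float(v) for k, v in d["evidence_enrichment"].items()}
    if "phenotype_couplings" in d:
        d["phenotype_couplings"] = {
            k: (int(v[0]), float(v[1]), float(v[2])) for k, v in d["phenotype_couplings"].items()
        }
    for key in ("module_sizes", "groups"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortConfig(**d)
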