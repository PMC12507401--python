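"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a 16S study of middle-aged and elderly urban adults:
compositional OTU counts with planted co-abundant guild blocks, sex-specific
linear age effects on guild abundances, disease labels that shift selected
guilds, and right-censored time-to-diabetes with death as a competing event.

Counts are drawn by (i) a latent per-guild log-normal factor model with a
stated within-block correlation and independence across blocks, (ii)
per-sample age/sex/disease shifts added on the log scale, (iii) closure to
relative abundances, (iv) multinomial sampling at a per-sample depth, and
(v) optional Bernoulli zero-inflation.  This is SparCC's own generative
assumption, which keeps oracle checks tractable; it does not reproduce
taxon-specific mean-variance relationships, phylogenetic structure, or
sequencing artifacts of real data.

Each sample carries a latent "microbiome aging deviation" (years).  It
shifts age-related guilds exactly as extra chronological age would and
enters the diabetes cause-specific log-hazard, so downstream recovery of
the microbial-age construct and of the prospective hazard can be tested
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .guilds import GuildPartition
from .io import (
    OtuTable,
    ValidationError,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)

_STAGES = {
    "assignments": 0,
    "latent": 1,
    "covariates": 2,
    "counts": 3,
    "zeros": 4,
    "survival": 5,
    "function": 6,
}

#: per-disease baseline prevalences (independent draws; the joint healthy
#: fraction lands near one half, as in large urban elderly cohorts)
DISEASE_PREVALENCE = {
    "t2dm": 0.15, "obesity": 0.10, "gout": 0.05, "fattydis": 0.15,
    "hypertension": 0.25, "stroke": 0.05, "heartdis": 0.05,
    "underweight": 0.03, "cancer": 0.05, "renal_failure": 0.01, "pd": 0.01,
}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Age effects are per-year shifts of the guild's latent log abundance,
    given as (beta_male, beta_female) per guild id; disease effects are
    additive latent log shifts for flagged samples.  Hazards are per year.
    """

    n_samples: int = 500
    n_otus: int = 300
    n_guilds: int = 10
    guild_size_range: tuple[int, int] = (10, 25)
    block_correlation: float = 0.8
    age_range: tuple[float, float] = (51.0, 89.0)
    frac_female: float = 0.5
    age_effects: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.02, 0.02), 2: (-0.02, -0.02), 3: (0.0, 0.03)}
    )
    disease_effects: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"t2dm": {1: 0.3, 2: 0.3}}
    )
    sequencing_depth_range: tuple[int, int] = (16332, 60000)
    zero_inflation: float = 0.05
    #: count scale of the dropout kernel: an entry with count c is masked with
    #: probability zero_inflation * exp(-c / dropout_scale_reads), so technical
    #: zeros concentrate on low-abundance entries as in real libraries
    dropout_scale_reads: float = 10.0
    t2dm_baseline_hazard: float = 0.003
    t2dm_age_deviation_loghr: float = 0.095
    death_hazard: float = 0.02
    seed: int = 0
    # latent-scale shape parameters
    latent_sigma: float = 1.0
    base_log_abundance_sd: float = 1.5
    deviation_sd_years: float = 2.0
    # predicted-function block
    n_pathways: int = 12
    pathway_loading: float = 10.0

    def validate(self) -> None:
        if self.n_guilds * self.guild_size_range[1] > self.n_otus:
            raise ValidationError(
                "n_guilds x max guild size exceeds n_otus "
                f"({self.n_guilds} x {self.guild_size_range[1]} > {self.n_otus})"
            )
        if self.guild_size_range[0] < 2 or (
            self.guild_size_range[0] > self.guild_size_range[1]
        ):
            raise ValidationError("guild_size_range must be an ordered pair >= 2")
        if not 0 < self.block_correlation < 1:
            raise ValidationError("block_correlation must lie in (0, 1)")
        if not 0 <= self.frac_female <= 1:
            raise ValidationError("frac_female must lie in [0, 1]")
        if not 0 <= self.zero_inflation <= 1:
            raise ValidationError("zero_inflation must lie in [0, 1]")
        for name in ("t2dm_baseline_hazard", "death_hazard"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.sequencing_depth_range[0] > self.sequencing_depth_range[1]:
            raise ValidationError("sequencing_depth_range must be ordered")
        if self.sequencing_depth_range[0] < 1:
            raise ValidationError("sequencing_depth_range min must be >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream: reproducible per stage under one global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_STAGES[stage],))
        )

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for k in ("guild_size_range", "age_range", "sequencing_depth_range"):
            if k in data:
                data[k] = tuple(data[k])
        if "age_effects" in data:
            data["age_effects"] = {
                int(k): tuple(v) for k, v in data["age_effects"].items()
            }
        if "disease_effects" in data:
            data["disease_effects"] = {
                d: {int(g): float(s) for g, s in eff.items()}
                for d, eff in data["disease_effects"].items()
            }
        return cls(**data)


def _assign_guilds(config: SynthConfig) -> dict[str, int]:
    """Planted truth: block guilds first, leftovers as independent background.

    Background OTUs get singleton guild ids after the planted blocks so that
    the truth partition is total.
    """
    rng = config.rng("assignments")
    lo, hi = config.guild_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_guilds)
    otus = [f"OTU{i+1:04d}" for i in range(config.n_otus)]
    assignment: dict[str, int] = {}
    pos = 0
    for gid, size in enumerate(sizes, start=1):
        for _ in range(int(size)):
            assignment[otus[pos]] = gid
            pos += 1
    next_gid = config.n_guilds + 1
    while pos < config.n_otus:
        assignment[otus[pos]] = next_gid
        next_gid += 1
        pos += 1
    return assignment


def generate_cohort(
    config: SynthConfig,
    return_latent: bool = False,
):
    """One cohort: counts, metadata (with survival fields) and the truth.

    The returned partition is the planted ground truth used by recovery
    tests; the metadata carries the latent aging deviation in the
    ``planted_deviation`` column.  With ``return_latent`` the samples x OTUs
    latent log-abundance matrix (before closure and sampling) is appended,
    for checks of the planted correlation structure.
    """
    config.validate()
    assignment = _assign_guilds(config)
    otus = sorted(assignment, key=lambda o: int(o[3:]))
    n, p = config.n_samples, config.n_otus
    samples = [f"S{i+1:05d}" for i in range(n)]

    # ---- covariates, diseases, deviation
    rng = config.rng("covariates")
    sex = np.where(rng.random(n) < config.frac_female, "female", "male")
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    bmi = np.clip(rng.normal(23.4, 2.2, size=n), 15.0, 40.0)
    energy = np.clip(rng.normal(2026.0, 540.0, size=n), 800.0, None)
    education = rng.choice([1, 2, 3, 4], size=n, p=[0.14, 0.38, 0.39, 0.09])
    meta = pd.DataFrame(
        {
            "age_years": age,
            "sex": sex,
            "bmi": bmi,
            "energy_kcal": energy,
            "education": education,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    behaviour_prev = {
        "exercise": (0.51, 0.52), "smoking": (0.20, 0.002),
        "drinking": (0.30, 0.02), "healthy_diet": (0.52, 0.57),
    }
    female = sex == "female"
    for behaviour, (pm, pf) in behaviour_prev.items():
        base = rng.random(n) < np.where(female, pf, pm)
        flip = rng.random(n) < 0.2
        meta[f"{behaviour}_baseline"] = base
        meta[f"{behaviour}_recent"] = np.where(flip, ~base, base)
    for disease, prev in DISEASE_PREVALENCE.items():
        meta[disease] = rng.random(n) < prev
    meta["antihypertensive"] = meta["hypertension"] & (rng.random(n) < 0.8)
    meta["hypoglycemic"] = meta["t2dm"] & (rng.random(n) < 0.7)
    meta["lipid_lowering"] = meta["fattydis"] & (rng.random(n) < 0.5)
    meta["analgesic_user"] = rng.random(n) < 0.01
    meta["hormone_user"] = rng.random(n) < 0.005
    meta["chfp_score"] = np.clip(rng.normal(30, 6, size=n).round(), 0, 45).astype(int)
    meta["fiber_g_day"] = np.round(rng.lognormal(2.4, 0.45, size=n), 2)
    deviation = rng.normal(0.0, config.deviation_sd_years, size=n)
    meta["planted_deviation"] = deviation

    # ---- latent log abundances
    rng = config.rng("latent")
    mu = rng.normal(0.0, config.base_log_abundance_sd, size=p)
    c = config.block_correlation
    eps = rng.standard_normal((n, p))
    z = np.sqrt(1.0 - c) * eps
    guild_of = np.asarray([assignment[o] for o in otus])
    for gid in range(1, config.n_guilds + 1):
        members = guild_of == gid
        factor = rng.standard_normal(n)
        z[:, members] += np.sqrt(c) * factor[:, None]
    background = guild_of > config.n_guilds
    z[:, background] = eps[:, background]  # fully independent background
    L = mu[None, :] + config.latent_sigma * z

    # age, deviation and disease shifts on the log scale
    age_centered = age - age.mean()
    for gid, (bm, bf) in config.age_effects.items():
        members = guild_of == gid
        beta = np.where(female, bf, bm)
        L[:, members] += (beta * (age_centered + deviation))[:, None]
    for disease, shifts in config.disease_effects.items():
        flag = meta[disease].to_numpy()
        for gid, shift in shifts.items():
            members = guild_of == gid
            L[np.ix_(flag, members)] += shift

    # ---- closure and multinomial sampling
    rng = config.rng("counts")
    rel = np.exp(L - L.max(axis=1, keepdims=True))
    rel /= rel.sum(axis=1, keepdims=True)
    depths = rng.integers(
        config.sequencing_depth_range[0],
        config.sequencing_depth_range[1] + 1,
        size=n,
    )
    counts = np.empty((n, p), dtype=np.int64)
    for s in range(n):
        counts[s] = rng.multinomial(int(depths[s]), rel[s])

    if config.zero_inflation > 0:
        rng = config.rng("zeros")
        p_drop = config.zero_inflation * np.exp(
            -counts / config.dropout_scale_reads
        )
        counts[rng.random((n, p)) < p_drop] = 0

    # ---- survival: exponential cause-specific hazards, admin censoring
    rng = config.rng("survival")
    lam_t2dm = config.t2dm_baseline_hazard * np.exp(
        config.t2dm_age_deviation_loghr * deviation
    ) / 12.0  # per month
    lam_death = np.full(n, config.death_hazard / 12.0)
    t_t2dm = rng.exponential(1.0 / lam_t2dm)
    t_death = rng.exponential(1.0 / lam_death)
    censor = rng.uniform(48.0, 84.0, size=n)
    followup = np.minimum.reduce([t_t2dm, t_death, censor])
    event = np.where(
        followup == t_t2dm, "t2dm", np.where(followup == t_death, "death", "none")
    )
    meta["followup_months"] = np.round(followup, 2)
    meta["event"] = event

    taxonomy = {
        o: (
            "k__Bacteria;p__SynthPhylum;c__SynthClass;o__SynthOrder;"
            f"f__SynthFamily_{assignment[o]};g__SynthGenus_{assignment[o]};s__{o}"
        )
        for o in otus
    }
    table = OtuTable(
        pd.DataFrame(counts, index=meta.index, columns=otus), taxonomy
    )
    truth = GuildPartition(assignment=assignment)
    if return_latent:
        latent = pd.DataFrame(L, index=meta.index, columns=otus)
        return table, meta, truth, latent
    return table, meta, truth


def generate_function_table(
    config: SynthConfig, partition: GuildPartition
) -> pd.DataFrame:
    """Per (sample, OTU, pathway) contribution percentages.

    Pathway i is planted on guild ``(i mod n_guilds) + 1``: its member OTUs
    receive a ``pathway_loading``-fold weight, so the planted guild carries
    the largest aggregated mean contribution.  Contributions are closed to
    100% per sample and pathway.
    """
    config.validate()
    otus = sorted(partition.assignment, key=str)
    if not otus:
        raise ValidationError("partition covers no OTUs")
    if config.n_pathways == 0:
        return pd.DataFrame(
            columns=["sample_id", "otu_id", "pathway", "contribution_pct"]
        )
    rng = config.rng("function")
    n = config.n_samples
    samples = [f"S{i+1:05d}" for i in range(n)]
    guild_of = np.asarray([partition.assignment[o] for o in otus])
    frames = []
    for k in range(config.n_pathways):
        planted = (k % config.n_guilds) + 1
        weights = rng.gamma(1.0, 1.0, size=(n, len(otus)))
        weights[:, guild_of == planted] *= config.pathway_loading
        weights /= weights.sum(axis=1, keepdims=True)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(samples, len(otus)),
                    "otu_id": np.tile(otus, n),
                    "pathway": f"PWY{k+1:04d}",
                    "contribution_pct": (weights * 100.0).ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort(
    outdir, table: OtuTable, meta: pd.DataFrame, truth: GuildPartition,
    config: SynthConfig,
) -> None:
    """Write the four on-disk artifacts: counts, taxonomy, metadata, config."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_otu_table(table, outdir / "otu_table.tsv")
    write_taxonomy(table.taxonomy or {}, outdir / "taxonomy.tsv")
    write_metadata(meta, outdir / "metadata.tsv")
    truth.to_frame().to_csv(outdir / "truth_partition.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")
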