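"""Synthetic CTC qRT-PCR cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: stable reference-gene Ct, epithelial transcripts whose detection
tracks the sample's CTC count, a planted subset of genes differentially
expressed between responder classes (lower Ct, i.e. higher expression, in
poor responders), and censored progression-free survival drawn from
class-specific exponential distributions.  Responder labels are generated
first; expression and survival are conditioned on them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import json
import numpy as np
import pandas as pd

from .datatypes import (
    CT_MAX,
    DEFAULT_REFERENCE_GENES,
    GOOD,
    POOR,
    ROLE_EPITHELIAL,
    ROLE_REFERENCE,
    ROLE_TARGET,
    ConfigurationError,
    CtMatrix,
)

#: targets with Ct beyond this cycle count are reported undetected
DETECTION_LIMIT_CT = 40.0
#: CTC count below which epithelial dropout applies (CellSearch convention)
LOW_CTC_THRESHOLD = 5
#: 9-month response cut-off (days) the simulated PFS is made consistent with
RESPONSE_CUTOFF_DAYS = 274.0


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the cohort generator.

    Units: Ct quantities in cycles, survival in days, rates/fractions as
    proportions in [0, 1].  ``effect_size`` is the Ct shift (cycles) applied
    to planted informative genes in poor responders; a positive value lowers
    their Ct (raises expression) in that class.
    """

    n_samples: int = 45
    n_genes: int = 96
    n_reference: int = 3
    n_epithelial: int = 12
    n_informative: int = 8
    effect_size: float = 2.5
    poor_fraction: float = 19 / 45
    reference_ct_mean: float = 22.0
    reference_ct_sd: float = 0.8
    noise_sd: float = 1.5
    dropout_rate_low_ctc: float = 0.5
    median_pfs_good_days: float = 550.0
    median_pfs_poor_days: float = 150.0
    censor_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "n_reference": self.n_reference,
            "n_epithelial": self.n_epithelial,
            "n_informative": self.n_informative,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer")
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_reference < 1:
            raise ConfigurationError("n_reference must be >= 1")
        if self.n_reference + self.n_epithelial + self.n_informative > self.n_genes:
            raise ConfigurationError(
                "n_reference + n_epithelial + n_informative must not exceed n_genes"
            )
        for name in ("poor_fraction", "dropout_rate_low_ctc", "censor_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("reference_ct_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("median_pfs_good_days", "median_pfs_poor_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.median_pfs_good_days <= RESPONSE_CUTOFF_DAYS:
            raise ConfigurationError(
                "median_pfs_good_days must exceed the "
                f"{RESPONSE_CUTOFF_DAYS:.0f}-day response cut-off"
            )
        if not 0 < self.reference_ct_mean <= CT_MAX:
            raise ConfigurationError(
                f"reference_ct_mean must lie in (0, {CT_MAX}]"
            )


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth it was built from."""

    ct: CtMatrix
    clinical: pd.DataFrame
    truth_informative_genes: list[str]
    truth_labels: pd.Series
    config: SimulationConfig
    #: +1 = higher expression in poor responders, -1 = higher in good
    truth_directions: pd.Series = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ct.to_tsv(out / "ct.tsv", out / "gene_roles.tsv")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="sample")
        truth = {
            "informative_genes": self.truth_informative_genes,
            "directions": (
                self.truth_directions.to_dict()
                if self.truth_directions is not None
                else {}
            ),
            "labels": self.truth_labels.to_dict(),
            "seed": self.config.seed,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _panel_genes(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    refs = list(DEFAULT_REFERENCE_GENES[: config.n_reference])
    refs += [f"REF{i:02d}" for i in range(len(refs) + 1, config.n_reference + 1)]
    epis = [f"EPI{i:02d}" for i in range(1, config.n_epithelial + 1)]
    n_targets = config.n_genes - config.n_reference - config.n_epithelial
    targets = [f"TGT{i:03d}" for i in range(1, n_targets + 1)]
    genes = refs + epis + targets
    roles = pd.Series(
        [ROLE_REFERENCE] * len(refs)
        + [ROLE_EPITHELIAL] * len(epis)
        + [ROLE_TARGET] * len(targets),
        index=genes,
        name="role",
    )
    return genes, roles


def _generate(config: SimulationConfig, null: bool) -> SimulatedCohort:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    genes, roles = _panel_genes(config)
    refs = list(roles.index[roles == ROLE_REFERENCE])
    epis = list(roles.index[roles == ROLE_EPITHELIAL])
    targets = list(roles.index[roles == ROLE_TARGET])

    # classes first; expression and survival are conditioned on them
    n_poor = int(round(config.poor_fraction * n))
    labels = np.array([POOR] * n_poor + [GOOD] * (n - n_poor))
    labels = labels[rng.permutation(n)]
    truth_labels = pd.Series(labels, index=samples, name="class")
    is_poor = labels == POOR

    informative = sorted(
        rng.choice(targets, size=config.n_informative, replace=False).tolist()
    )
    # direction of differential expression: most planted genes are higher
    # in poor responders, a minority higher in good responders (roughly a
    # 3:1 split), giving the signature the mixed-sign structure real
    # responder signatures show
    n_up_poor = int(np.ceil(0.75 * config.n_informative))
    directions = pd.Series(
        [1] * n_up_poor + [-1] * (config.n_informative - n_up_poor),
        index=informative,
        name="direction",
    )

    effect = 0.0 if null else config.effect_size
    # in a null cohort every label-conditioned quantity (CTC burden, PFS)
    # is driven by an independent permutation of the classes instead
    outcome_class = rng.permutation(is_poor) if null else is_poor

    # CTC burden: lognormal around the cohort-typical median, heavier in
    # poor responders (high counts carry worse prognosis)
    ctc = np.rint(
        np.exp(rng.normal(np.log(8.0) + np.where(outcome_class, 1.0, 0.0), 1.5, n))
    ).astype(int)
    ctc = np.clip(ctc, 0, None)
    low_ctc = ctc < LOW_CTC_THRESHOLD

    ct = pd.DataFrame(np.nan, index=genes, columns=samples)

    # stable references
    ct.loc[refs] = rng.normal(
        config.reference_ct_mean, config.reference_ct_sd, (len(refs), n)
    )

    # epithelial transcripts: expression rises (Ct falls) with CTC count
    epi_base = 36.0 - 1.2 * np.log2(ctc + 1.0)
    epi_offset = rng.normal(0.0, 1.0, len(epis))
    epi_ct = (
        epi_base[None, :]
        + epi_offset[:, None]
        + rng.normal(0.0, config.noise_sd, (len(epis), n))
    )
    dropout = rng.random((len(epis), n)) < config.dropout_rate_low_ctc
    epi_ct[dropout & low_ctc[None, :]] = np.nan
    ct.loc[epis] = epi_ct

    # target panel: per-gene baseline plus noise; planted genes shifted to
    # lower Ct (higher expression) in poor responders
    base = rng.uniform(26.0, 34.0, len(targets))
    tgt_ct = base[:, None] + rng.normal(0.0, config.noise_sd, (len(targets), n))
    tgt = pd.DataFrame(tgt_ct, index=targets, columns=samples)
    poor_samples = truth_labels.index[is_poor]
    for g in informative:
        # direction +1: lower Ct (higher expression) in poor responders
        tgt.loc[g, poor_samples] -= directions[g] * effect
    ct.loc[targets] = tgt

    # detection limit: very late amplification is reported as undetected
    vals = ct.to_numpy()
    vals[vals > DETECTION_LIMIT_CT] = np.nan
    vals[~np.isnan(vals)] = np.clip(vals[~np.isnan(vals)], 1e-3, None)
    ct = pd.DataFrame(vals, index=genes, columns=samples)

    # survival, consistent with the class definition (poor = progression or
    # death before the response cut-off; follow-up, hence censoring, only
    # after it — as in a cohort whose censored patients were all followed
    # at least that long):
    #  * poor responders: event always observed; time drawn from an
    #    exponential with median median_pfs_poor_days conditioned on
    #    falling before the cut-off (the realized class median is
    #    therefore somewhat smaller than the nominal parameter);
    #  * good responders: event time cutoff + exponential (the memoryless
    #    tail) scaled so the class median equals median_pfs_good_days,
    #    independently censored after the cutoff at censor_rate.
    cutoff = RESPONSE_CUTOFF_DAYS
    pfs = np.empty(n)
    event = np.empty(n, dtype=bool)

    poor_idx = np.flatnonzero(outcome_class)
    good_idx = np.flatnonzero(~outcome_class)

    r_poor = np.log(2.0) / config.median_pfs_poor_days
    u = rng.random(poor_idx.size) * (1.0 - np.exp(-r_poor * cutoff))
    pfs[poor_idx] = np.minimum(cutoff - 1.0, -np.log(1.0 - u) / r_poor)
    event[poor_idx] = True

    tail_median = config.median_pfs_good_days - cutoff
    r_good = np.log(2.0) / tail_median
    t_event = cutoff + rng.exponential(1.0 / r_good, good_idx.size)
    if config.censor_rate > 0:
        r_cens = r_good * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = cutoff + rng.exponential(1.0 / r_cens, good_idx.size)
    else:
        t_cens = np.full(good_idx.size, np.inf)
    pfs[good_idx] = np.minimum(t_event, t_cens)
    event[good_idx] = t_event <= t_cens

    pfs = np.maximum(1.0, np.rint(pfs))

    clinical = pd.DataFrame(
        {
            "pfs_days": pfs,
            "event": event,
            "ctc_count": ctc,
            "ctc_group": np.where(ctc >= LOW_CTC_THRESHOLD, ">=5", "<5"),
            "dfi_group": rng.choice(
                ["<=5y", ">5y", "metastatic-at-diagnosis"],
                size=n,
                p=[16 / 45, 21 / 45, 8 / 45],
            ),
            "relapse_site": rng.choice(
                ["visceral", "non-visceral"], size=n, p=[19 / 45, 26 / 45]
            ),
            "treatment": "AI",
        },
        index=samples,
    )

    return SimulatedCohort(
        ct=CtMatrix(ct, roles),
        clinical=clinical,
        truth_informative_genes=informative,
        truth_labels=truth_labels,
        config=config,
        truth_directions=directions,
    )


def generate_cohort(config: Optional[SimulationConfig] = None) -> SimulatedCohort:
    """Generate a cohort with the planted class effect.

    Fully reproducible from ``config.seed``.
    """
    return _generate(config or SimulationConfig(), null=False)


def generate_null_cohort(config: Optional[SimulationConfig] = None) -> SimulatedCohort:
    """Generate a cohort with no class effect and PFS independent of labels."""
    config = config or SimulationConfig()
    return _generate(replace(config, effect_size=0.0), null=True)
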