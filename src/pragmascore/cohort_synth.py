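"""Synthetic trial-cohort generator for pipeline testing and calibration.

No clinical imaging from the reanalysed trial is available, so every
pipeline stage is exercised on a synthetic cohort that emulates its
published summary statistics: 238 enrolled patients of whom 210 contribute
scans, ~195 scorable start-of-study (SOS) and ~196 end-of-study (EOS)
scans, PRAGMA %Disease at SOS with mean 9.96 and SD 7.58 (range 0-35.5),
48-week progression of 0.212 on the square-root scale, no treatment-arm or
tobramycin effect, and covariates (age 22.7 +/- 9.7 y, FEV1 %predicted
61.3 +/- 14.7, ~50/50 sex).

Mechanism (all on the square-root scale, which is where the percent scores
are homoscedastic and close to normal — squaring back injects exactly the
mean-dependent heteroscedasticity that motivates the sqrt transform in the
analysis):

* ``sqrt(%Disease)_ij = m + u_i + delta I(EOS) + e_ij``, squared and
  clipped to [0, 100].  ``m`` and the total variance come from an exact
  moment inversion of the published mean/SD (if sqrt(Y) ~ N(m, s^2) then
  E Y = m^2 + s^2, Var Y = 2 s^4 + 4 m^2 s^2); the residual SD default
  (0.48) is calibrated so the fitted time-effect SE reproduces the
  published 0.079.
* %Disease is split into bronchiectasis / mucus plugging / AWT by a
  patient-level Dirichlet draw centred on the published subscore shares
  (bronchiectasis dominant, AWT near zero); atelectasis is a small
  zero-inflated add-on.  Subscore progression is therefore emergent from
  the %Disease progression.
* CF-CT %Disease is an affine function of sqrt(%Disease) plus noise,
  calibrated to the published cross-system correlation (r = 0.74) and the
  CF-CT %Disease moments; CF-CT component scores scale with it.
* FEV1 %predicted gets a patient-level mean plus a small non-significant
  decline.

Annotation-level realizations invert the scoring systems: grid labels are
dealt to lung cells by largest-remainder rounding of the target volume
fractions (so re-scoring a realized grid reproduces the target subscores
to within one cell, i.e. 100/n_lung_cells percentage points), and CF-CT
extent codes are distributed over the six regions to match component
targets up to the rubric's coarse quantization.

All generation is seed-deterministic; each patient has an independent
spawned substream, so enlarging the cohort never reshuffles existing
patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import (
    COMPONENTS,
    REGIONS,
    CellLabel,
    GridAnnotation,
    LobeAssessmentSet,
    LABEL_CODES,
    NON_LUNG_CODE,
)
from .scoring import CFCT_COMPONENT_MAXIMA, CFCT_TOTAL_MAX

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "realize_annotations",
    "realize_lobe_assessments",
    "generate_rescore",
    "sqrt_scale_moments",
    "largest_remainder_counts",
]

#: Published CF-CT component means (% of maximal score) used as the shape
#: of the synthetic CF-CT component profile.
CFCT_COMPONENT_MEANS = {
    "bronchiectasis": 15.03,
    "awt": 17.81,
    "mucus_plugging": 29.05,
    "parenchyma": 14.54,
}


def sqrt_scale_moments(mean: float, sd: float) -> tuple[float, float]:
    """(m, s) with sqrt(Y) ~ N(m, s^2) matching raw mean/SD of Y exactly."""
    disc = mean**2 - sd**2 / 2.0
    if disc < 0:
        raise ValueError(f"no squared-normal score has mean {mean} and SD {sd}")
    u = mean - math.sqrt(disc)
    return math.sqrt(mean - u), math.sqrt(u)


def largest_remainder_counts(fractions: Sequence[float], total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by largest-remainder rounding."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.sum() > 1.0 + 1e-9:
        raise ValueError("fractions sum to more than 1")
    quota = fractions * total
    counts = np.floor(quota).astype(int)
    short = int(round(quota.sum())) - int(counts.sum())
    if short > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:short]] += 1
    return counts


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults reproduce the published cohort."""

    n_enrolled: int = 238
    n_with_scan: int = 210
    p_sos_scorable: float = 195.0 / 210.0
    p_eos_scorable: float = 196.0 / 210.0
    sos_disease_mean: float = 9.96
    sos_disease_sd: float = 7.58
    progression_sqrt_disease: float = 0.212
    #: Published per-subscore sqrt-scale time effects, kept as reference
    #: targets; the generator derives subscores from %Disease, so their
    #: realized progression is emergent, not injected.
    progression_sqrt_mp: float = 0.175
    progression_sqrt_be: float = 0.139
    residual_sd_sqrt: float = 0.48
    subscore_fractions: tuple[float, float, float] = (0.782, 0.217, 0.001)  # BE, MP, AWT
    dirichlet_concentration: float = 25.0
    atl_prob: float = 0.5
    atl_mean: float = 0.24
    arm_fraction_placebo: float = 0.5
    tobra_fraction: float = 0.5
    age_mean: float = 22.7
    age_sd: float = 9.7
    fev1_mean: float = 61.3
    fev1_sd: float = 14.7
    fev1_progression: float = -0.6
    fev1_residual_sd: float = 5.0
    cfct_disease_mean: float = 17.94
    cfct_disease_sd: float = 6.71
    cfct_corr: float = 0.74
    # Effects not present in the reanalysed trial; exposed for calibration
    # studies (e.g. type-I error checks need them at 0).
    arm_effect_sqrt: float = 0.0
    tobra_effect_sqrt: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_with_scan <= self.n_enrolled):
            raise ValueError("need 0 <= n_with_scan <= n_enrolled")
        for p in (self.p_sos_scorable, self.p_eos_scorable, self.arm_fraction_placebo, self.tobra_fraction, self.atl_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sos_disease_mean > 100 or self.sos_disease_mean < 0:
            raise ValueError("infeasible %Disease mean")
        if self.sos_disease_sd < 0 or self.cfct_disease_sd < 0:
            raise ValueError("SDs must be >= 0")
        _, s = sqrt_scale_moments(self.sos_disease_mean, self.sos_disease_sd)
        if self.residual_sd_sqrt >= s:
            raise ValueError(
                "residual_sd_sqrt exceeds the total sqrt-scale SD implied by the score moments"
            )


@dataclass
class SyntheticCohort:
    """A generated cohort: covariates, per-visit scores, optional annotations."""

    config: CohortConfig
    patients: pd.DataFrame
    scores: pd.DataFrame  # tidy: patient_id, visit, system, subscore, value
    annotations: dict[tuple[str, str], GridAnnotation] = field(default_factory=dict)
    lobe_assessments: dict[tuple[str, str], LobeAssessmentSet] = field(default_factory=dict)

    def long_table(self, outcomes: Sequence[str] | None = None) -> pd.DataFrame:
        """Long cohort table (patient, visit, arm, tobramycin, outcome, value)."""
        merged = self.scores.merge(
            self.patients[["patient_id", "arm", "tobramycin"]], on="patient_id"
        )
        outcome = np.where(
            merged["system"] == "clinical",
            merged["subscore"],
            merged["system"] + "_" + merged["subscore"],
        )
        out = merged.assign(outcome=outcome)[
            ["patient_id", "visit", "arm", "tobramycin", "outcome", "value"]
        ]
        if outcomes is not None:
            out = out[out["outcome"].isin(outcomes)].reset_index(drop=True)
        return out

    def scorable_visits(self) -> list[tuple[str, str]]:
        mask = self.scores["system"] == "pragma"
        pairs = self.scores.loc[mask, ["patient_id", "visit"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]


def _cfct_link(config: CohortConfig) -> tuple[float, float, float]:
    """Affine + noise link from sqrt(%Disease) to sqrt(CF-CT %Disease)."""
    m_p, s_p = sqrt_scale_moments(config.sos_disease_mean, config.sos_disease_sd)
    m_c, s_c = sqrt_scale_moments(config.cfct_disease_mean, config.cfct_disease_sd)
    beta = config.cfct_corr * s_c / s_p
    resid = s_c * math.sqrt(max(0.0, 1.0 - config.cfct_corr**2))
    alpha = m_c - beta * m_p
    return alpha, beta, resid


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate one synthetic cohort (deterministic given ``config.seed``)."""
    if config is None:
        config = CohortConfig()
    m, s = sqrt_scale_moments(config.sos_disease_mean, config.sos_disease_sd)
    sigma = config.residual_sd_sqrt
    tau = math.sqrt(s**2 - sigma**2)
    alpha_c, beta_c, resid_c = _cfct_link(config)
    fev1_between = math.sqrt(max(0.0, config.fev1_sd**2 - config.fev1_residual_sd**2))
    frac_alpha = config.dirichlet_concentration * np.asarray(config.subscore_fractions)

    children = np.random.SeedSequence(config.seed).spawn(config.n_enrolled)
    pat_rows = []
    score_rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i:04d}"
        # Fixed draw order keeps substreams stable across config tweaks.
        sex = "F" if rng.random() < 0.5 else "M"
        age = max(6.0, rng.normal(config.age_mean, config.age_sd))
        arm = "placebo" if rng.random() < config.arm_fraction_placebo else "ataluren"
        tobra = "yes" if rng.random() < config.tobra_fraction else "no"
        sos_ok = rng.random() < config.p_sos_scorable
        eos_ok = rng.random() < config.p_eos_scorable
        u = rng.normal(0.0, tau)
        e1, e2 = rng.normal(0.0, sigma, 2)
        fracs = rng.dirichlet(frac_alpha)
        atl_present = rng.random(2) < config.atl_prob
        atl_val = rng.exponential(config.atl_mean, 2) * atl_present
        fev1_u = rng.normal(0.0, fev1_between)
        fev1_e = rng.normal(0.0, config.fev1_residual_sd, 2)
        cfct_e = rng.normal(0.0, resid_c, 2)

        has_scan = i < config.n_with_scan
        pat_rows.append(
            {
                "patient_id": pid,
                "arm": arm,
                "tobramycin": tobra,
                "sex": sex,
                "age": age,
                "has_scan": has_scan,
                "sos_scorable": bool(has_scan and sos_ok),
                "eos_scorable": bool(has_scan and eos_ok),
            }
        )
        if not has_scan:
            continue
        shift = config.arm_effect_sqrt * (arm == "placebo") + config.tobra_effect_sqrt * (
            tobra == "yes"
        )
        for visit, ok, e, atl, f_e, c_e in (
            ("SOS", sos_ok, e1, atl_val[0], fev1_e[0], cfct_e[0]),
            ("EOS", eos_ok, e2, atl_val[1], fev1_e[1], cfct_e[1]),
        ):
            if not ok:
                continue
            x = m + u + e + shift
            if visit == "EOS":
                x += config.progression_sqrt_disease
            x = max(0.0, x)
            disease = min(100.0, x**2)
            be, mp, awt = fracs * disease
            atl = float(min(atl, 100.0 - disease))
            normal = 100.0 - disease - atl
            for name, value in (
                ("bronchiectasis", be),
                ("mucus_plugging", mp),
                ("awt", awt),
                ("atelectasis", atl),
                ("normal", normal),
                ("disease", disease),
            ):
                score_rows.append((pid, visit, "pragma", name, float(value)))

            xc = max(0.0, alpha_c + beta_c * x + c_e)
            cfct_dis = min(100.0, xc**2)
            scale = cfct_dis / config.cfct_disease_mean
            comp_pct = {
                c: float(np.clip(CFCT_COMPONENT_MEANS[c] * scale, 0.0, 100.0))
                for c in COMPONENTS
            }
            total = (
                sum(comp_pct[c] * CFCT_COMPONENT_MAXIMA[c] for c in COMPONENTS)
                / CFCT_TOTAL_MAX
            )
            for c in COMPONENTS:
                score_rows.append((pid, visit, "cfct", c, comp_pct[c]))
            score_rows.append((pid, visit, "cfct", "disease", float(cfct_dis)))
            score_rows.append((pid, visit, "cfct", "total", float(total)))

            fev1 = max(0.0, config.fev1_mean + fev1_u + f_e
                       + (config.fev1_progression if visit == "EOS" else 0.0))
            score_rows.append((pid, visit, "clinical", "fev1_percent_predicted", float(fev1)))

    patients = pd.DataFrame(pat_rows)
    scores = pd.DataFrame(
        score_rows, columns=["patient_id", "visit", "system", "subscore", "value"]
    )
    return SyntheticCohort(config=config, patients=patients, scores=scores)


def _lung_mask(rows: int, cols: int) -> np.ndarray:
    """Inscribed-ellipse lung mask shared by all slices."""
    r = (np.arange(rows) + 0.5 - rows / 2.0) / (rows / 2.0)
    c = (np.arange(cols) + 0.5 - cols / 2.0) / (cols / 2.0)
    mask = (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0
    if not mask.any():
        mask[rows // 2, cols // 2] = True
    return mask


def realize_annotations(
    cohort: SyntheticCohort,
    grid_rows: int = 20,
    grid_cols: int = 20,
    seed: int = 0,
) -> SyntheticCohort:
    """Realize a grid annotation per scorable visit matching its subscores.

    Labels are dealt to lung cells by largest-remainder rounding of the
    target volume fractions and then shuffled, so
    ``pragma_subscores(realization)`` reproduces every target subscore to
    within 100 / n_lung_cells percentage points.
    """
    mask = _lung_mask(grid_rows, grid_cols)
    n_lung_slice = int(mask.sum())
    n_lung = n_lung_slice * 10
    wide = cohort.scores[cohort.scores["system"] == "pragma"].pivot_table(
        index=["patient_id", "visit"], columns="subscore", values="value"
    )
    order = [
        CellLabel.BRONCHIECTASIS,
        CellLabel.MUCUS_PLUGGING,
        CellLabel.AWT,
        CellLabel.ATELECTASIS,
    ]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    annotations = dict(cohort.annotations)
    for (pid, visit), row in wide.iterrows():
        fractions = [
            row["bronchiectasis"] / 100.0,
            row["mucus_plugging"] / 100.0,
            row["awt"] / 100.0,
            row["atelectasis"] / 100.0,
        ]
        counts = largest_remainder_counts(fractions, n_lung)
        labels = np.full(n_lung, LABEL_CODES[CellLabel.NORMAL], dtype=np.uint8)
        start = 0
        for lab, k in zip(order, counts):
            labels[start : start + k] = LABEL_CODES[lab]
            start += k
        rng.shuffle(labels)
        slices = []
        pos = 0
        for _ in range(10):
            sl = np.full((grid_rows, grid_cols), NON_LUNG_CODE, dtype=np.uint8)
            sl[mask] = labels[pos : pos + n_lung_slice]
            pos += n_lung_slice
            slices.append(sl)
        annotations[(pid, visit)] = GridAnnotation(pid, visit, slices)
    return replace(cohort, annotations=annotations)


def realize_lobe_assessments(cohort: SyntheticCohort, seed: int = 0) -> SyntheticCohort:
    """Realize CF-CT extent codes per scorable visit from component targets.

    Component raw-score targets are converted to extent units and spread
    over the six regions as evenly as the 0-3 codes allow; the rubric's
    coarse quantization is part of what the realization emulates.
    """
    from .scoring import DEFAULT_CFCT_WEIGHTS

    wide = cohort.scores[cohort.scores["system"] == "cfct"].pivot_table(
        index=["patient_id", "visit"], columns="subscore", values="value"
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    assessments = dict(cohort.lobe_assessments)
    n_regions = len(REGIONS)
    for (pid, visit), row in wide.iterrows():
        entries = {}
        for c in COMPONENTS:
            target_units = row[c] / 100.0 * CFCT_COMPONENT_MAXIMA[c] / DEFAULT_CFCT_WEIGHTS[c]
            u = int(np.clip(round(target_units), 0, 3 * n_regions))
            q, r = divmod(u, n_regions)
            extents = np.array([q + 1] * r + [q] * (n_regions - r))
            rng.shuffle(extents)
            for region, e in zip(REGIONS, extents):
                entries[(region, c)] = int(e)
        assessments[(pid, visit)] = LobeAssessmentSet(pid, visit, entries)
    return replace(cohort, lobe_assessments=assessments)


def generate_rescore(
    cohort: SyntheticCohort,
    icc_target: float = 0.85,
    n_rescored: int = 20,
    seed: int = 0,
    systems: Sequence[str] = ("pragma", "cfct"),
) -> pd.DataFrame:
    """Second-occasion rescoring of a random scan subset.

    A uniform without-replacement subset of ``n_rescored`` scorable visits
    is rescored as ``second = first + noise``; the noise variance is set
    from the first-occasion score variance v so that the two-way
    consistency ICC of the resulting table converges to ``icc_target``
    (the ANOVA estimator's population value under this scheme is
    ``v / (v + sigma^2 / 2)``, hence ``sigma^2 = 2 v (1 - t) / t``).

    Returns a tidy table with an ``occasion`` column (1 = original
    scoring, 2 = rescoring).
    """
    if not (0.0 < icc_target <= 1.0):
        raise ValueError("icc_target must lie in (0, 1]")
    visits = cohort.scorable_visits()
    if len(visits) < n_rescored:
        raise ValueError(f"only {len(visits)} scorable visits; cannot rescore {n_rescored}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen_idx = rng.choice(len(visits), size=n_rescored, replace=False)
    chosen = {visits[i] for i in chosen_idx}

    scores = cohort.scores
    mask = scores["system"].isin(systems) & scores.apply(
        lambda r: (r["patient_id"], r["visit"]) in chosen, axis=1
    )
    first = scores.loc[mask].copy()
    rows = []
    for (system, subscore), block in first.groupby(["system", "subscore"]):
        v = float(block["value"].var(ddof=1)) if len(block) > 1 else 0.0
        if icc_target == 1.0 or v == 0.0:
            noise_sd = 0.0
        else:
            noise_sd = math.sqrt(2.0 * v * (1.0 - icc_target) / icc_target)
        noise = rng.normal(0.0, noise_sd, len(block)) if noise_sd > 0 else np.zeros(len(block))
        for (_, r), nz in zip(block.iterrows(), noise):
            rows.append((r["patient_id"], r["visit"], system, subscore, 1, r["value"]))
            rows.append((r["patient_id"], r["visit"], system, subscore, 2, r["value"] + nz))
    return pd.DataFrame(
        rows, columns=["patient_id", "visit", "system", "subscore", "occasion", "value"]
    )
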