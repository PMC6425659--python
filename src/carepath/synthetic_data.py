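"""Seeded synthetic linked-record generator.

Real person-level linked unscheduled-care extracts cannot be shared, so every
downstream stage is exercised against generated bundles whose marginal
structure matches a national mental-health ambulance cohort: a heavy-tailed
repeat-call distribution, a pathway-type mixture dominated by S / SE / SEA /
SEM-SM, log-normal emergency-department lengths of stay with medians near
150 min (completed treatment) and 100 min (self-discharge), a ~17%
self-discharge proportion positively coupled to alcohol intoxication
(risk ratio 1.49) and to subsequent repeat calls (risk ratio 1.25), and a
one-year mortality mix of suicide / mental-behavioural / other causes.

Joint structure is induced by multiplicative risk scaling: the configured
self-discharge and >=1-repeat probabilities are treated as *marginals* and
the unexposed baselines are solved from the exposure prevalence, so that the
analysis pipeline recovers both the marginal proportions and the configured
risk ratios. Generation is a pure function of the configuration, including
its seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
import yaml

from .analysis import analyze_bundle
from .cohort import AMPDS_INCLUSION_CODES
from .followup import REPEAT_BINS, REPEAT_BIN_LABELS
from .pathways import PATHWAY_CLASSES
from .records_io import LinkedRecordBundle, empty_bundle

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9

#: Open-ended top repeat bin is materialized as 15..101 calls (uniform).
_TOP_BIN_HIGH = 101

#: AMPDS chapter 23 (intentional poisoning) is an inclusion-list chapter, not
#: a full code; generated chapter-23 calls carry a concrete member code.
_CHAPTER23_CODES = ("23B01", "23C01", "23D01")

#: Pool of plausible non-inclusion final AMPDS codes for all-cause repeats.
_NON_MH_CODES = ("06D01", "10D02", "12D01", "17A01", "26A01", "31D02")

_COHORT_N = 6802  # cohort-scale denominators behind the default mixtures
_CALLS_N = 9014


def _norm(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


@dataclasses.dataclass
class SimulationConfig:
    """All generator distributions, effect sizes and the seed.

    Defaults are the study-scale calibration: repeat-bin and pathway-class
    mixtures from the observed cohort frequencies, marginal self-discharge
    0.17 with RR 1.49 for alcohol-flagged calls, RR 1.25 of >=1 repeat call
    after an index self-discharge, within-1-day / later-within-year death
    probabilities of 39/6802 and 240/6802, and a suicide /
    mental-behavioural / other cause mix of 97/64/118 of 279 deaths.
    """

    n_persons: int = _COHORT_N
    index_year: int = 2011
    repeat_call_distribution: dict[str, float] = dataclasses.field(
        default_factory=lambda: _norm(
            dict(zip(REPEAT_BIN_LABELS, (3564, 1294, 646, 366, 218, 459, 155, 100)))
        )
    )
    pathway_mixture: dict[str, float] = dataclasses.field(
        default_factory=lambda: _norm(
            dict(zip(PATHWAY_CLASSES, (800, 3369, 995, 656, 982)))
        )
    )
    ed_los_completed_median_min: float = 150.7
    ed_los_selfdischarge_median_min: float = 100.5
    ed_los_sigma: float = 0.6
    selfdischarge_prob: float = 0.17
    alcohol_prob: float = 1816 / _CALLS_N
    rr_alcohol_on_selfdischarge: float = 1.49
    rr_selfdischarge_on_repeat: float = 1.25
    death_within_1day_prob: float = 39 / _COHORT_N
    death_within_year_prob: float = 240 / _COHORT_N
    cause_mixture: dict[str, float] = dataclasses.field(
        default_factory=lambda: _norm(
            {"suicide": 97, "mental_behavioural": 64, "other": 118}
        )
    )
    mh_code_mixture: dict[str, float] = dataclasses.field(
        default_factory=lambda: _norm(
            {
                "25A01": 4315,
                "25B02": 2615,
                "25B01": 1117,
                "23": 697,
                "25B03": 129,
                "25B04": 79,
                "09E03": 43,
                "17D02J": 7,
                "17D03J": 6,
                "25D01": 6,
            }
        )
    )
    prop_under_16: float = 0.05
    male_prob: float = 0.522
    drug_prob: float = 94 / _CALLS_N
    lowest_priority_prob: float = 0.486
    repeat_nonmh_code_prob: float = 0.2
    triage_missing_prob: float = 0.339
    acute_los_median_days: float = 1.0
    psych_los_median_days: float = 8.0
    admission_los_sigma: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        for name in (
            "selfdischarge_prob",
            "alcohol_prob",
            "death_within_1day_prob",
            "death_within_year_prob",
            "prop_under_16",
            "male_prob",
            "drug_prob",
            "lowest_priority_prob",
            "repeat_nonmh_code_prob",
            "triage_missing_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "ed_los_completed_median_min",
            "ed_los_selfdischarge_median_min",
            "acute_los_median_days",
            "psych_los_median_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rr_alcohol_on_selfdischarge", "rr_selfdischarge_on_repeat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, keys in (
            ("repeat_call_distribution", REPEAT_BIN_LABELS),
            ("pathway_mixture", PATHWAY_CLASSES),
            ("cause_mixture", ("suicide", "mental_behavioural", "other")),
            ("mh_code_mixture", tuple(AMPDS_INCLUSION_CODES)),
        ):
            vec = getattr(self, name)
            if set(vec) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            if any(p < 0 or p > 1 for p in vec.values()):
                raise ValueError(f"{name} entries must be probabilities")
            if abs(sum(vec.values()) - 1.0) > _PROB_TOL:
                raise ValueError(f"{name} must sum to 1 within {_PROB_TOL}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(**overrides) -> SimulationConfig:
    """The study-scale default configuration (optionally overridden)."""
    cfg = dataclasses.replace(SimulationConfig(), **overrides)
    cfg.validate()
    return cfg


class _PersonState:
    __slots__ = (
        "pid",
        "n_contacts",
        "index_start",
        "index_end",
        "exposed_sd",
        "index_date",
        "alcohol",
    )

    def __init__(self, pid):
        self.pid = pid
        self.n_contacts = 0


class _Generator:
    """One generation run; all randomness flows through ``self.rng``."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.persons: list[dict] = []
        self.calls: list[dict] = []
        self.ed: list[dict] = []
        self.admissions: list[dict] = []
        self.deaths: list[dict] = []

        a = config.alcohol_prob
        rr = config.rr_alcohol_on_selfdischarge
        p0 = config.selfdischarge_prob / (1 - a + a * rr)
        p1 = p0 * rr
        if p1 > 1:
            logger.warning("capping alcohol-scaled self-discharge probability at 1")
            p1 = 1.0
        self.p_sd = (p0, p1)
        self.class_labels = list(config.pathway_mixture)
        self.class_probs = np.array(list(config.pathway_mixture.values()))
        self.mh_codes = list(config.mh_code_mixture)
        self.mh_probs = np.array(list(config.mh_code_mixture.values()))
        self.cause_labels = list(config.cause_mixture)
        self.cause_probs = np.array(list(config.cause_mixture.values()))
        self.bin_probs = np.array(
            [config.repeat_call_distribution[lab] for lab in REPEAT_BIN_LABELS]
        )

    # -- elementary draws ---------------------------------------------------

    def _minutes(self, lo: int, hi: int) -> pd.Timedelta:
        return pd.Timedelta(minutes=int(self.rng.integers(lo, hi + 1)))

    def _lognormal_minutes(self, median: float, sigma: float) -> pd.Timedelta:
        los = math.exp(self.rng.normal(math.log(median), sigma))
        return pd.Timedelta(minutes=max(1, round(los)))

    def _draw_code(self) -> str:
        code = self.mh_codes[self.rng.choice(len(self.mh_codes), p=self.mh_probs)]
        if code == "23":
            code = _CHAPTER23_CODES[self.rng.integers(0, len(_CHAPTER23_CODES))]
        return code

    def _draw_letters(self) -> str:
        label = self.class_labels[self.rng.choice(len(self.class_labels), p=self.class_probs)]
        if label == "S":
            return "S"
        if label == "SE":
            return "SE"
        if label == "SEA":
            return "SEA"
        if label == "SEM_SM":
            return "SEM" if self.rng.random() < 0.5 else "SM"
        # OTHER: S followed by 2-10 letters from {E, A, M} (no further
        # ambulance calls, so repeat counting stays exact), not equal to a
        # named class.
        while True:
            length = int(self.rng.integers(3, 12))
            tail = "".join(
                "EAM"[self.rng.integers(0, 3)] for _ in range(length - 1)
            )
            letters = "S" + tail
            if letters not in ("SEA", "SEM"):
                return letters

    # -- pathway materialization -------------------------------------------

    def _materialize_pathway(self, st: _PersonState, t0: pd.Timestamp, code: str):
        """Emit one care pathway's contacts starting with an S call at t0.

        Returns (any_selfdischarge, pathway_end_time).
        """
        cfg = self.cfg
        rng = self.rng
        letters = self._draw_letters()
        # Alcohol intoxication is a person-level propensity: alcohol-related
        # presentations cluster within individuals, and a shared flag keeps
        # the alcohol/self-discharge coupling intact even when a frequent
        # caller's episodes chain into one pathway. The call-level marginal
        # still equals alcohol_prob.
        alcohol = st.alcohol
        p_sd = self.p_sd[1] if alcohol else self.p_sd[0]

        def next_cid():
            st.n_contacts += 1
            return f"{st.pid}-C{st.n_contacts:04d}"

        start = t0
        end = start + self._minutes(20, 90)
        self.calls.append(
            {
                "contact_id": next_cid(),
                "person_id": st.pid,
                "start_datetime": start,
                "end_datetime": end,
                "final_ampds_code": code,
                "alcohol_flag": alcohol,
                "drug_flag": rng.random() < cfg.drug_prob,
                "lowest_priority_flag": rng.random() < cfg.lowest_priority_prob,
                "transported": len(letters) > 1 and letters[1] == "E",
            }
        )
        sd_any = False
        prev_end = end
        for i, letter in enumerate(letters[1:], start=1):
            start = prev_end + self._minutes(5, 1200)  # gap < 24 h by construction
            if letter == "E":
                nxt = letters[i + 1] if i + 1 < len(letters) else None
                if nxt in ("A", "M"):
                    disposition = "admitted"
                elif nxt is None:
                    disposition = (
                        "self_discharge" if rng.random() < p_sd else "completed"
                    )
                else:
                    disposition = "completed"
                median = (
                    cfg.ed_los_selfdischarge_median_min
                    if disposition == "self_discharge"
                    else cfg.ed_los_completed_median_min
                )
                end = start + self._lognormal_minutes(median, cfg.ed_los_sigma)
                sd_any = sd_any or disposition == "self_discharge"
                triage = (
                    None
                    if rng.random() < cfg.triage_missing_prob
                    else int(rng.integers(1, 6))
                )
                self.ed.append(
                    {
                        "contact_id": next_cid(),
                        "person_id": st.pid,
                        "start_datetime": start,
                        "end_datetime": end,
                        "disposition": disposition,
                        "triage_category": triage,
                    }
                )
            else:
                ward = "acute" if letter == "A" else "psychiatric"
                median_days = (
                    cfg.acute_los_median_days
                    if ward == "acute"
                    else cfg.psych_los_median_days
                )
                end = start + self._lognormal_minutes(
                    median_days * 1440, cfg.admission_los_sigma
                )
                self.admissions.append(
                    {
                        "contact_id": next_cid(),
                        "person_id": st.pid,
                        "start_datetime": start,
                        "end_datetime": end,
                        "ward_type": ward,
                    }
                )
            prev_end = end
        return sd_any, prev_end

    # -- person-level passes ------------------------------------------------

    def _generate_person(self, i: int, year_minutes: int, year_start) -> _PersonState:
        cfg = self.cfg
        rng = self.rng
        st = _PersonState(f"P{i:06d}")
        st.alcohol = rng.random() < cfg.alcohol_prob
        under16 = rng.random() < cfg.prop_under_16
        age = int(rng.integers(1, 16)) if under16 else int(rng.integers(16, 91))
        st.index_start = year_start + pd.Timedelta(
            minutes=int(rng.integers(0, year_minutes))
        )
        st.index_date = st.index_start.normalize()
        # DOB offset < 365 d preserves the drawn attained age at the index call.
        dob = (
            st.index_date
            - pd.DateOffset(years=age)
            - pd.Timedelta(days=int(rng.integers(0, 365)))
        )
        self.persons.append(
            {
                "person_id": st.pid,
                "date_of_birth": dob,
                "sex": "male" if rng.random() < cfg.male_prob else "female",
                "resident_in_scope": True,
            }
        )
        st.exposed_sd, st.index_end = self._materialize_pathway(
            st, st.index_start, self._draw_code()
        )
        return st

    def _generate_repeats(self, states: list[_PersonState]) -> None:
        cfg = self.cfg
        rng = self.rng
        if not states:
            return
        p_exp = float(np.mean([s.exposed_sd for s in states]))
        p_base = 1.0 - self.bin_probs[0]  # marginal P(>=1 repeat)
        rr = cfg.rr_selfdischarge_on_repeat
        p0 = p_base / (1 - p_exp + p_exp * rr)
        p1 = p0 * rr
        if p1 > 1:
            logger.warning("capping self-discharge-scaled repeat probability at 1")
            p1 = 1.0
        if p_base > 0:
            cond = self.bin_probs[1:] / self.bin_probs[1:].sum()
        else:
            cond = None
        for st in states:
            p_ge1 = p1 if st.exposed_sd else p0
            if cond is None or rng.random() >= p_ge1:
                continue
            j = 1 + int(rng.choice(len(cond), p=cond))
            _, lo, hi = REPEAT_BINS[j]
            hi = _TOP_BIN_HIGH if hi is None else hi
            k = int(rng.integers(lo, hi + 1))
            # Place repeat calls after the index pathway has closed (plus a
            # >24 h buffer so they never chain into it) and within the
            # one-year counting window. Calls go into evenly spaced slots
            # with jitter so consecutive repeat pathways rarely fall within
            # the 24-h chaining rule of one another.
            lo_t = st.index_end + pd.Timedelta(hours=25)
            hi_t = st.index_start + pd.Timedelta(days=365)
            span = int((hi_t - lo_t) / pd.Timedelta(minutes=1))
            if span <= k:
                logger.warning("no room for repeat calls for %s; skipped", st.pid)
                continue
            slot = span / k
            offsets = [
                int(i * slot + rng.uniform(0, slot / 2)) for i in range(k)
            ]
            for off in offsets:
                t = lo_t + pd.Timedelta(minutes=int(off))
                if rng.random() < cfg.repeat_nonmh_code_prob:
                    code = _NON_MH_CODES[rng.integers(0, len(_NON_MH_CODES))]
                else:
                    code = self._draw_code()
                self._materialize_pathway(st, t, code)

    def _generate_deaths(self, states: list[_PersonState]) -> None:
        cfg = self.cfg
        rng = self.rng
        d1 = cfg.death_within_1day_prob
        dy = cfg.death_within_year_prob
        for st in states:
            u = rng.random()
            if u < d1:
                offset = int(rng.integers(0, 2))  # index day or the next
            elif u < d1 + dy:
                offset = int(rng.integers(2, 366))
            else:
                continue
            cause = self.cause_labels[
                self.rng.choice(len(self.cause_labels), p=self.cause_probs)
            ]
            self.deaths.append(
                {
                    "person_id": st.pid,
                    "date_of_death": st.index_date + pd.Timedelta(days=offset),
                    "cause_category": cause,
                }
            )

    def run(self) -> LinkedRecordBundle:
        cfg = self.cfg
        if cfg.n_persons == 0:
            return empty_bundle()
        year_start = pd.Timestamp(cfg.index_year, 1, 1)
        year_minutes = int(
            (pd.Timestamp(cfg.index_year + 1, 1, 1) - year_start)
            / pd.Timedelta(minutes=1)
        )
        states = [
            self._generate_person(i, year_minutes, year_start)
            for i in range(cfg.n_persons)
        ]
        self._generate_repeats(states)
        self._generate_deaths(states)
        empty = empty_bundle()

        def frame(rows, template):
            if not rows:
                return template
            df = pd.DataFrame(rows, columns=list(template.columns))
            if "triage_category" in df.columns:
                df["triage_category"] = df["triage_category"].astype("Int64")
            return df

        return LinkedRecordBundle(
            persons=frame(self.persons, empty.persons),
            calls=frame(self.calls, empty.calls),
            ed=frame(self.ed, empty.ed),
            admissions=frame(self.admissions, empty.admissions),
            deaths=frame(self.deaths, empty.deaths),
        )


def generate_bundle(config: SimulationConfig) -> LinkedRecordBundle:
    """Generate a linked-record bundle; pure function of the config + seed."""
    return _Generator(config).run()


@dataclasses.dataclass
class GeneratorSummary:
    """Empirical counterparts of the configured distributions, measured by
    running the actual analysis pipeline on a bundle."""

    n_persons: int
    n_cohort: int
    n_mh_calls_index_year: int
    n_callers_index_year: int
    pathway_mixture: dict[str, float] | None
    repeat_distribution: dict[str, float] | None
    selfdischarge_prop: float | None
    alcohol_prop: float | None
    rr_alcohol_on_selfdischarge: float | None
    rr_selfdischarge_on_repeat: float | None
    ed_los_completed_median_min: float | None
    ed_los_selfdischarge_median_min: float | None
    death_within_1day_prop: float | None
    death_within_year_prop: float | None
    cause_mixture: dict[str, float] | None
    prop_under_16: float | None


def summarize_bundle(
    bundle: LinkedRecordBundle,
    year: int | None = None,
    config: SimulationConfig | None = None,
) -> GeneratorSummary:
    """Measure a bundle's empirical distributions via the analysis pipeline,
    for comparison against the generating configuration."""
    if year is None:
        if config is not None:
            year = config.index_year
        elif len(bundle.calls):
            year = int(bundle.calls["start_datetime"].dt.year.min())
        else:
            year = 0
    if bundle.n_persons == 0:
        return GeneratorSummary(
            0, 0, 0, 0, None, None, None, None, None, None, None, None, None,
            None, None, None,
        )
    res = analyze_bundle(bundle, year)
    n_callers = res.mh_calls["person_id"].nunique() if len(res.mh_calls) else 0
    n_cohort = res.n_cohort
    mix = None
    if len(res.index_rows):
        vc = res.index_rows["pathway_class"].value_counts(normalize=True)
        mix = {c: float(vc.get(c, 0.0)) for c in PATHWAY_CLASSES}
    rep = None
    if len(res.repeat_dist):
        rep = dict(zip(res.repeat_dist["repeat_bin"], res.repeat_dist["pct"] / 100.0))
    ed_rows = res.pathway_rows.loc[res.pathway_rows["ed_ending"]]
    sd_prop = float(ed_rows["selfdischarge"].mean()) if len(ed_rows) else None
    alco = float(res.mh_calls["alcohol_flag"].mean()) if len(res.mh_calls) else None
    rr_a = res.tests.get("rr_alcohol_selfdischarge")
    rr_r = res.tests.get("rr_selfdischarge_repeat")
    ms = res.mortality_summary
    deaths_1yr = ms.deaths_1yr
    causes = None
    if deaths_1yr:
        died = res.mortality.loc[
            res.mortality["died_within_1day"] | res.mortality["died_1day_to_1yr"]
        ]
        vc = died["cause_category"].value_counts(normalize=True)
        causes = {c: float(vc.get(c, 0.0)) for c in ("suicide", "mental_behavioural", "other")}
    n_seen = n_cohort + sum(res.exclusions.values())
    return GeneratorSummary(
        n_persons=bundle.n_persons,
        n_cohort=n_cohort,
        n_mh_calls_index_year=len(res.mh_calls),
        n_callers_index_year=int(n_callers),
        pathway_mixture=mix,
        repeat_distribution=rep,
        selfdischarge_prop=sd_prop,
        alcohol_prop=alco,
        rr_alcohol_on_selfdischarge=(rr_a.effect if rr_a else None),
        rr_selfdischarge_on_repeat=(rr_r.effect if rr_r else None),
        ed_los_completed_median_min=(
            res.ed_los_completed.median if res.ed_los_completed else None
        ),
        ed_los_selfdischarge_median_min=(
            res.ed_los_selfdischarge.median if res.ed_los_selfdischarge else None
        ),
        death_within_1day_prop=(ms.deaths_1d / n_cohort if n_cohort else None),
        death_within_year_prop=(ms.deaths_late / n_cohort if n_cohort else None),
        cause_mixture=causes,
        prop_under_16=(
            res.exclusions.get("under_16", 0) / n_seen if n_seen else None
        ),
    )
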