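"""Synthetic query-log generator with planted, recoverable ground truth.

Real search logs of this kind are proprietary, so the package ships a
generator that emulates their statistical structure at desk scale:

* every user emits background queries as a homogeneous Poisson process over
  the log span; each background query expresses one concept (symptom or
  condition) with configured probability, or is a concept-free filler;
* an *adopter* subpopulation additionally develops an interest in celiac
  disease: a first celiac-related query (CRQ) at an index time t0 drawn
  uniformly from the index period (the last calendar month of the span),
  with configurable per-concept rate multipliers in the 14-day window
  before t0 (the planted "antecedent symptom" signal);
* adopters split into passing (CRQs on one calendar day) and sustained
  interest (CRQs on 1 + Geometric extra distinct days, mean three days in
  total), mirroring the observed ~93%/7% mixture;
* recipe queries are emitted at their own Poisson rate; after t0 an
  adopter's dish choice shifts toward gluten-free dishes by a configurable
  multiplier (the planted dietary shift);
* a small fraction of adopters emit one first-person self-identification
  query after t0.

Non-adopters never emit queries containing "celiac" or "gluten" (their dish
vocabulary excludes gluten-free dishes); all adopter CRQs occur at or after
t0, so the washout filter holds by construction.  Identical (config, seed)
produce byte-identical logs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from querysignal.ingest import LogSpan, write_query_log
from querysignal.cohort import CohortConfig, CohortMember, build_cohort
from querysignal.lexicon import Lexicon
from querysignal.signal import WindowSpec, query_ratio_table

__all__ = [
    "SimConfig",
    "GroundTruth",
    "GroundTruthUser",
    "RecoveryReport",
    "simulate",
    "generate_logs",
    "recover_parameters",
    "DEFAULT_CONCEPT_PROBS",
    "DEFAULT_DISHES",
]

#: Background per-query concept probabilities (remainder is filler).  The
#: concepts are drawn from the demonstration symptom/condition lexicons with
#: rates a general search population plausibly shows.
DEFAULT_CONCEPT_PROBS: dict[str, float] = {
    "diarrhea": 0.020,
    "headache": 0.020,
    "pain": 0.018,
    "cough": 0.015,
    "bloating": 0.012,
    "anxiety": 0.015,
    "depression": 0.012,
    "fatigue": 0.012,
    "nausea": 0.010,
    "vomiting": 0.008,
    "abdominal pain": 0.008,
    "weight loss": 0.008,
    "itch": 0.006,
    "bleeding": 0.006,
    "rash": 0.006,
    "migraine": 0.008,
    "asthma": 0.008,
    "influenza": 0.008,
    "lactose intolerance": 0.004,
    "irritable bowel syndrome": 0.004,
}

#: Dish vocabulary: name -> (relative weight, is gluten-free).  Gluten-free
#: dish names contain the word "gluten", so those queries are CRQs.
DEFAULT_DISHES: dict[str, tuple[float, bool]] = {
    "gluten free pie crust": (1.0, True),
    "gluten free pumpkin bread": (1.0, True),
    "gluten free banana bread": (1.0, True),
    "gluten free peanut butter cookies": (1.0, True),
    "gluten free chocolate chip cookies": (1.0, True),
    "gluten free pancakes": (1.0, True),
    "gluten free pizza crust": (1.0, True),
    "gluten free muffins": (1.0, True),
    "gluten free bread": (1.0, True),
    "gluten free brownies": (1.0, True),
    "honey cake": (1.0, False),
    "earthquake cake": (1.0, False),
    "cucumber salad": (1.0, False),
    "egg salad": (1.0, False),
    "pasta salad": (1.0, False),
    "broccoli salad": (1.0, False),
    "fish tacos": (1.0, False),
    "ratatouille": (1.0, False),
    "tomato pie": (1.0, False),
    "tuna noodle casserole": (1.0, False),
}

_FILLERS = (
    "weather today",
    "best pizza near me",
    "football scores",
    "movie showtimes tonight",
    "cheap flights to denver",
    "how to tie a tie",
    "bank opening hours",
    "crossword puzzle answers",
    "used cars for sale",
    "phone repair shop",
    "election news",
    "traffic on highway 9",
)

_CONCEPT_TEMPLATES = ("{p}", "{p} symptoms", "{p} treatment", "what causes {p}", "{p} remedies")
_PAIR_TEMPLATE = "{p} and {q}"
_RECIPE_TEMPLATES = ("{d} recipe", "how to make {d}", "easy {d} recipe")
_CRQ_TEMPLATES = (
    "celiac disease",
    "celiac symptoms",
    "what is celiac disease",
    "gluten intolerance",
    "gluten sensitivity symptoms",
    "celiac disease diet",
)
_SELF_ID_TEXT = "i have celiac disease can i eat rice"

_SECOND = 1.0 / 86400.0  # one second, in days


@dataclass
class SimConfig:
    """Simulator parameters.

    Defaults encode the emulated study conditions: a ten-month span whose
    last calendar month is the index period, a 7% sustained share among
    adopters, 14-day analysis windows, and no planted signal (null
    multipliers, no dietary shift).
    """

    n_users: int = 500
    span: LogSpan = field(default_factory=lambda: LogSpan(date(2017, 1, 1), date(2017, 10, 31)))
    background_rate: float = 1.0  # mean background queries per user-day
    concept_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONCEPT_PROBS))
    adopter_fraction: float = 0.05
    sustained_fraction: float = 0.07
    pre_window_multipliers: dict[str, float] = field(default_factory=dict)
    window_days: int = 14
    post_recipe_shift: float = 1.0
    recipe_rate: float = 0.1  # mean recipe queries per user-day
    dish_probs: dict[str, tuple[float, bool]] = field(default_factory=lambda: dict(DEFAULT_DISHES))
    self_id_prob: float = 0.0005
    multi_concept_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ValueError("n_users must be >= 0")
        for name, p in [
            ("adopter_fraction", self.adopter_fraction),
            ("sustained_fraction", self.sustained_fraction),
            ("self_id_prob", self.self_id_prob),
            ("multi_concept_prob", self.multi_concept_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(p < 0 or p > 1 for p in self.concept_probs.values()):
            raise ValueError("concept probabilities must lie in [0, 1]")
        if sum(self.concept_probs.values()) > 1.0 + 1e-9:
            raise ValueError("concept probabilities must sum to <= 1")
        if any(r <= 0 for r in self.pre_window_multipliers.values()):
            raise ValueError("pre-window multipliers must be > 0")
        if self.post_recipe_shift <= 0:
            raise ValueError("post_recipe_shift must be > 0")
        unknown = set(self.pre_window_multipliers) - set(self.concept_probs)
        if unknown:
            raise ValueError(f"multipliers for unknown concepts: {sorted(unknown)}")
        # The span must cover the 9-month washout plus the index month.
        if (pd.Timestamp(self.index_start) - pd.DateOffset(months=9)) < pd.Timestamp(self.span.start):
            raise ValueError(
                "log span too short: it must cover a 9-month washout before the index month"
            )

    @property
    def index_start(self) -> date:
        """First day of the index period (the last calendar month of the span)."""
        return self.span.end.replace(day=1)

    @property
    def index_end(self) -> date:
        return self.span.end

    def cohort_config(self) -> CohortConfig:
        """The cohort filter settings matching this simulated design."""
        history_cutoff = (pd.Timestamp(self.index_start) - pd.DateOffset(months=1)).date()
        return CohortConfig(
            index_start=self.index_start,
            index_end=self.index_end,
            washout_months=9,
            history_cutoff=history_cutoff,
            window_days=self.window_days,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["span"] = {"start": self.span.start.isoformat(), "end": self.span.end.isoformat()}
        d["dish_probs"] = {k: [w, gf] for k, (w, gf) in self.dish_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "span" in d and isinstance(d["span"], dict):
            d["span"] = LogSpan(
                date.fromisoformat(d["span"]["start"]), date.fromisoformat(d["span"]["end"])
            )
        if "dish_probs" in d:
            d["dish_probs"] = {k: (float(v[0]), bool(v[1])) for k, v in d["dish_probs"].items()}
        return cls(**d)


@dataclass
class GroundTruthUser:
    adopter: bool
    t0: str | None = None  # ISO timestamp of the planted index CRQ
    planted_sustained: bool | None = None
    n_crq_days_emitted: int = 0
    self_identified: bool = False


@dataclass
class GroundTruth:
    """Planted per-user and per-concept truth for recovery tests."""

    users: dict[str, GroundTruthUser]
    concept_multipliers: dict[str, float]
    dish_shift: float
    gluten_free_dishes: list[str]
    n_records: int
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "users": {u: asdict(g) for u, g in self.users.items()},
            "concept_multipliers": self.concept_multipliers,
            "dish_shift": self.dish_shift,
            "gluten_free_dishes": self.gluten_free_dishes,
            "n_records": self.n_records,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            users={u: GroundTruthUser(**g) for u, g in payload["users"].items()},
            concept_multipliers=payload["concept_multipliers"],
            dish_shift=payload["dish_shift"],
            gluten_free_dishes=payload["gluten_free_dishes"],
            n_records=payload["n_records"],
            config=payload["config"],
        )

    @property
    def n_adopters(self) -> int:
        return sum(g.adopter for g in self.users.values())

    @property
    def realized_sustained_fraction(self) -> float | None:
        """Share of adopters whose emitted log has CRQs on more than one day."""
        if self.n_adopters == 0:
            return None
        multi = sum(g.adopter and g.n_crq_days_emitted > 1 for g in self.users.values())
        return multi / self.n_adopters


def _day_to_ts(span_start: datetime, off_days: np.ndarray, n_days: int) -> pd.DatetimeIndex:
    secs = np.floor(off_days * 86400.0).astype(np.int64)
    secs = np.clip(secs, 0, n_days * 86400 - 1)  # keep every record inside the span
    return pd.Timestamp(span_start) + pd.to_timedelta(secs, unit="s")


def simulate(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a query-log frame and its ground truth.

    The frame has the standard log columns, stably sorted by
    ``(user_id, timestamp)``; raw text carries light capitalization and
    punctuation noise that normalization removes.  Deterministic per
    (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    n_days = config.span.n_days
    span_start = config.span.start_instant
    idx_start_off = (config.index_start - config.span.start).days
    idx_len = (config.index_end - config.index_start).days + 1
    w = float(config.window_days)

    concepts = list(config.concept_probs)
    probs = np.array([config.concept_probs[c] for c in concepts], dtype=float)
    p_filler = 1.0 - probs.sum()
    draw_p = np.append(probs, p_filler)

    dishes = list(config.dish_probs)
    dish_w = np.array([config.dish_probs[d][0] for d in dishes], dtype=float)
    gf_mask = np.array([config.dish_probs[d][1] for d in dishes], dtype=bool)
    w_nongf = np.where(gf_mask, 0.0, dish_w)
    pre_dish_p = w_nongf / w_nongf.sum() if w_nongf.sum() > 0 else None
    w_post = np.where(gf_mask, dish_w * config.post_recipe_shift, dish_w)
    post_dish_p = w_post / w_post.sum()

    # Pre-expanded text tables for vectorized assembly (all already normalized).
    tmpl_table = np.array(
        [[t.format(p=c) for t in _CONCEPT_TEMPLATES] for c in concepts], dtype=object
    ).reshape(len(concepts), len(_CONCEPT_TEMPLATES))
    filler_arr = np.array(_FILLERS, dtype=object)
    dish_table = np.array(
        [[t.format(d=d) for t in _RECIPE_TEMPLATES] for d in dishes], dtype=object
    ).reshape(max(len(dishes), 1), len(_RECIPE_TEMPLATES)) if dishes else None
    crq_arr = np.array(_CRQ_TEMPLATES, dtype=object)

    users: list[str] = []
    offs_all: list[np.ndarray] = []
    texts_all: list[np.ndarray] = []
    truth_users: dict[str, GroundTruthUser] = {}
    width = max(4, len(str(max(config.n_users - 1, 0))))
    zip_pool = [f"{z:05d}" for z in rng.integers(10000, 99999, size=max(config.n_users, 1))]
    user_zip: dict[str, str] = {}

    for u in range(config.n_users):
        uid = f"u{u:0{width}d}"
        user_zip[uid] = zip_pool[u] if rng.random() < 0.9 else ""
        offs: list[np.ndarray] = []
        texts: list[np.ndarray] = []

        adopter = rng.random() < config.adopter_fraction
        t0_off: float | None = None
        sustained = False
        if adopter:
            t0_off = idx_start_off + rng.random() * idx_len
            sustained = bool(rng.random() < config.sustained_fraction)

        # Background concept/filler stream.
        n_bg = rng.poisson(config.background_rate * n_days)
        bg_off = rng.random(n_bg) * n_days
        kind = rng.choice(len(concepts) + 1, size=n_bg, p=draw_p)
        # Pre-window thinning for multipliers < 1.
        keep = np.ones(n_bg, dtype=bool)
        if adopter:
            for ci, c in enumerate(concepts):
                r = config.pre_window_multipliers.get(c, 1.0)
                if r < 1.0:
                    in_win = (kind == ci) & (bg_off >= t0_off - w) & (bg_off < t0_off)
                    drop = in_win & (rng.random(n_bg) > r)
                    keep &= ~drop
        bg_off, kind = bg_off[keep], kind[keep]
        n_kept = len(bg_off)
        tmpl_idx = rng.integers(0, len(_CONCEPT_TEMPLATES), size=n_kept)
        fill_idx = rng.integers(0, len(_FILLERS), size=n_kept)
        pair = rng.random(n_kept) < config.multi_concept_prob
        pair_partner = rng.integers(0, max(len(concepts), 1), size=n_kept)
        bg_texts = np.empty(n_kept, dtype=object)
        is_fill = kind == len(concepts)
        bg_texts[is_fill] = filler_arr[fill_idx[is_fill]]
        is_con = ~is_fill
        if is_con.any():
            bg_texts[is_con] = tmpl_table[kind[is_con], tmpl_idx[is_con]]
            pr = is_con & pair
            if pr.any():
                bg_texts[pr] = [
                    f"{concepts[k]} and {concepts[q]}"
                    for k, q in zip(kind[pr], pair_partner[pr])
                ]
        offs.append(bg_off)
        texts.append(bg_texts)

        # Planted pre-window elevation (superposed extra queries, r > 1).
        if adopter:
            for ci, c in enumerate(concepts):
                r = config.pre_window_multipliers.get(c, 1.0)
                if r > 1.0:
                    lam = config.background_rate * probs[ci] * w * (r - 1.0)
                    n_extra = rng.poisson(lam)
                    if n_extra:
                        lo = max(t0_off - w, 0.0)
                        e_off = lo + rng.random(n_extra) * max(t0_off - _SECOND - lo, 0.0)
                        e_tmpl = rng.integers(0, len(_CONCEPT_TEMPLATES), size=n_extra)
                        offs.append(e_off)
                        texts.append(tmpl_table[ci, e_tmpl])

        # Recipe stream.  The dietary shift toward gluten-free dishes applies
        # from t0 onward for sustained adopters, and only during day t0 for
        # passing adopters (whose interest dies with the index day — this is
        # what keeps them "passing": no gluten-containing queries later).
        n_rc = rng.poisson(config.recipe_rate * n_days)
        if n_rc and dishes:
            rc_off = rng.random(n_rc) * n_days
            rc_dish = np.zeros(n_rc, dtype=np.int64)
            if adopter:
                shift_end = n_days if sustained else min(float(int(t0_off) + 1), n_days)
                shifted = (rc_off >= t0_off) & (rc_off < shift_end)
                # shifted recipe queries may contain "gluten": keep them
                # strictly after t0 and inside the span
                rc_off[shifted] = np.clip(
                    rc_off[shifted], t0_off + _SECOND, n_days - _SECOND
                )
            else:
                shifted = np.zeros(n_rc, dtype=bool)
            base = ~shifted
            sel = np.ones(n_rc, dtype=bool)
            if pre_dish_p is not None:
                rc_dish[base] = rng.choice(len(dishes), size=int(base.sum()), p=pre_dish_p)
            else:
                sel &= shifted  # no non-gluten-free dishes configured
            n_sh = int(shifted.sum())
            if n_sh:
                rc_dish[shifted] = rng.choice(len(dishes), size=n_sh, p=post_dish_p)
            rc_off, rc_dish = rc_off[sel], rc_dish[sel]
            rc_tmpl = rng.integers(0, len(_RECIPE_TEMPLATES), size=len(rc_off))
            offs.append(rc_off)
            texts.append(dish_table[rc_dish, rc_tmpl])

        # Adopter CRQs and self-identification.
        g = GroundTruthUser(adopter=adopter)
        if adopter:
            t0_ts = span_start + timedelta(seconds=math.floor(t0_off * 86400.0))
            g.t0 = t0_ts.strftime("%Y-%m-%dT%H:%M:%S")
            g.planted_sustained = sustained
            offs.append(np.array([t0_off]))
            texts.append(crq_arr[[rng.integers(0, len(_CRQ_TEMPLATES))]])
            # extra same-day CRQs
            n_same = rng.poisson(0.7)
            if n_same:
                day_end = min(float(int(t0_off) + 1), n_days)
                s_off = t0_off + _SECOND + rng.random(n_same) * max(
                    day_end - t0_off - 2 * _SECOND, 0.0
                )
                offs.append(np.minimum(s_off, n_days - _SECOND))
                texts.append(crq_arr[rng.integers(0, len(_CRQ_TEMPLATES), size=n_same)])
            if sustained:
                later_days = np.arange(int(t0_off) + 1, n_days)
                n_extra_days = min(int(rng.geometric(0.5)), len(later_days))
                if n_extra_days:
                    chosen = rng.choice(later_days, size=n_extra_days, replace=False)
                    offs.append(chosen + rng.random(n_extra_days))
                    texts.append(crq_arr[rng.integers(0, len(_CRQ_TEMPLATES), size=n_extra_days)])
            if rng.random() < config.self_id_prob:
                if sustained:
                    s = t0_off + _SECOND + rng.random() * max(n_days - t0_off - 2 * _SECOND, 0.0)
                else:  # passing users stop querying about celiac after day t0
                    day_end = min(float(int(t0_off) + 1), n_days)
                    s = t0_off + _SECOND + rng.random() * max(day_end - t0_off - 2 * _SECOND, 0.0)
                offs.append(np.array([min(s, n_days - _SECOND)]))
                texts.append(np.array([_SELF_ID_TEXT], dtype=object))
                g.self_identified = True
        truth_users[uid] = g

        u_off = np.concatenate(offs) if offs else np.zeros(0)
        users.extend([uid] * len(u_off))
        offs_all.append(u_off)
        texts_all.append(np.concatenate(texts) if texts else np.zeros(0, dtype=object))

    all_off = np.concatenate(offs_all) if offs_all else np.zeros(0)
    all_texts = (
        np.concatenate(texts_all) if texts_all else np.zeros(0, dtype=object)
    )
    n_records = len(all_texts)

    # raw-text noise (capitalization, punctuation) removed by normalization
    from querysignal.ingest import normalize_text

    noisy = rng.random(n_records)
    raw_texts = all_texts.copy()
    cap = noisy < 0.15
    punct = noisy > 0.97
    raw_texts[cap] = [t.capitalize() for t in raw_texts[cap]]
    raw_texts[punct] = [t + "?" for t in raw_texts[punct]]
    norm_texts = all_texts.copy()
    changed = cap | punct
    norm_texts[changed] = [normalize_text(t) for t in raw_texts[changed]]

    df = pd.DataFrame(
        {
            "user_id": pd.Series(users, dtype="object"),
            "timestamp": _day_to_ts(span_start, all_off, n_days),
            "raw_text": raw_texts,
            "norm_text": norm_texts,
            "zip_code": [user_zip[u] for u in users],
        }
    )
    df = df.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)

    # Recount emitted CRQ days from the log itself so the ground truth is
    # consistent with the emitted records (gluten-free recipe queries after
    # t0 add CRQ days).
    from querysignal.cohort import _CRQ_RE  # local import to avoid cycle at module load

    crq_rows = df[df["norm_text"].str.contains(_CRQ_RE)]
    day_counts = crq_rows.groupby("user_id")["timestamp"].apply(lambda s: s.dt.date.nunique())
    for uid, g in truth_users.items():
        if g.adopter:
            g.n_crq_days_emitted = int(day_counts.get(uid, 0))

    truth = GroundTruth(
        users=truth_users,
        concept_multipliers=dict(config.pre_window_multipliers),
        dish_shift=config.post_recipe_shift,
        gluten_free_dishes=[d for d in dishes if config.dish_probs[d][1]],
        n_records=n_records,
        config=config.to_dict(),
    )
    return df, truth


def generate_logs(
    config: SimConfig, out_log: str | Path, out_truth: str | Path
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate and write the query-log TSV and ground-truth JSON."""
    df, truth = simulate(config)
    write_query_log(df, out_log)
    truth.to_json(out_truth)
    return df, truth


@dataclass
class RecoveryReport:
    """Comparison of pipeline estimates against the planted truth.

    Each entry carries the estimate, the planted value, and a Monte-Carlo
    standard error; ``flags`` lists quantities outside 3 standard errors.
    """

    entries: list[dict]
    flags: list[str]

    def as_dict(self) -> dict:
        return {"entries": self.entries, "flags": self.flags}


def recover_parameters(
    records: pd.DataFrame,
    truth: GroundTruth,
    lexicon: Lexicon,
    members: list[CohortMember] | None = None,
    min_support: int = 10,
) -> RecoveryReport:
    """Check QR estimates and the sustained share against planted values.

    For each lexicon concept with a planted multiplier (and, as a null
    check, every unplanted concept, expected QR 1), the estimated pooled
    query ratio must fall within 3 delta-method standard errors of the
    planted value; the realized sustained share is compared with the
    estimated one from the cohort labels (binomial SE).
    """
    config = SimConfig.from_dict(truth.config)
    if members is None:
        members, _ = build_cohort(records, config.cohort_config())
    span = config.span
    window = WindowSpec(config.window_days)
    table = query_ratio_table(
        members, records, lexicon, window, min_support=min_support, span=span
    )
    entries: list[dict] = []
    flags: list[str] = []
    for res in table:
        if not res.defined or res.standard_error is None:
            continue
        planted = truth.concept_multipliers.get(res.concept_id, 1.0)
        dev = abs(res.qr - planted)
        ok = dev <= 3.0 * res.standard_error
        entries.append(
            {
                "quantity": f"qr:{res.concept_id}",
                "estimate": res.qr,
                "planted": planted,
                "se": res.standard_error,
                "within_3se": ok,
            }
        )
        if not ok:
            flags.append(f"qr:{res.concept_id}")

    realized = truth.realized_sustained_fraction
    if realized is not None and members:
        est = sum(m.interest == "sustained" for m in members) / len(members)
        se = math.sqrt(max(est * (1 - est), 1e-12) / len(members))
        ok = abs(est - realized) <= 3.0 * se
        entries.append(
            {
                "quantity": "sustained_fraction",
                "estimate": est,
                "planted": realized,
                "se": se,
                "within_3se": ok,
            }
        )
        if not ok:
            flags.append("sustained_fraction")
    return RecoveryReport(entries=entries, flags=flags)
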