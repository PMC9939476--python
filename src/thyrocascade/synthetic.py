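"""Synthetic cohorts: seeded simulation and deterministic reconstruction.

Two generators live here.

:func:`simulate_cohort` draws independent patient records from a
categorical model — outcome ~ Bernoulli(prevalence), FNA category from an
outcome-conditional vector, frozen-section category from an
(outcome, FNA)-conditional vector — and is the workhorse behind the
property tests.  Its default parameters are the empirical frequencies of
the reconstruction below, so simulated cohorts have the statistical
structure the analysis assumes.

:func:`reconstruct_paper_cohort` deterministically builds a patient-level
cohort of 3807 records that reproduces, cell for cell, every published
margin of the study it emulates: the FNA x outcome and FS x outcome
tables, the staged-rule combined x outcome table, and the printed
FNA -> FS flow counts.  Joint cells not forced by those constraints are
filled by proportional allocation with largest-remainder rounding (flows)
and a deterministic capped-transportation solve (outcome split); no
randomness is involved, and two builds are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms.flow import edmonds_karp

from . import vocab
from .cohort import Cohort, PatientRecord
from .errors import ConfigError, InfeasibilityError
from .contingency import ContingencyTable

_PROB_TOL = 1e-9

# ---------------------------------------------------------------------------
# Reconstruction constraints (published margins)
# ---------------------------------------------------------------------------

# (malignant, benign) in fixed vocabulary order
_FNA_BY_OUTCOME = {
    "VI": (2566, 21), "V": (647, 18), "IV": (2, 20),
    "III": (277, 65), "II": (20, 96), "I": (32, 43),
}
_FS_BY_OUTCOME = {
    "MALIGNANCY": (3334, 0), "SUSPICIOUS": (80, 22),
    "BENIGN": (126, 239), "INDETERMINATE": (4, 2),
}
_COMBINED_BY_OUTCOME = {
    "MALIGNANCY": (3448, 21), "SUSPICIOUS": (49, 16),
    "BENIGN": (45, 224), "INDETERMINATE": (2, 2),
}
# printed FNA -> FS flows: counts into FS MALIGNANCY for the categories the
# text names, and the benign-or-indeterminate FS total per Bethesda category
_MALIGNANCY_FLOWS = {"VI": 2452, "V": 608, "III": 232}
_BENIGN_OR_INDET_BY_FNA = {"VI": 98, "V": 38, "IV": 18, "III": 74, "II": 100, "I": 43}

# outcome-conditional covariate margins (counts among malignant / benign)
_COVARIATES = {
    "age_lt55": {"MALIGNANT": 2790, "BENIGN": 159},
    "sex_female": {"MALIGNANT": 2655, "BENIGN": 215},
    # diameter strata <5 / 5-10 / >=10 mm
    "diameter": {"MALIGNANT": (812, 1652, 1080), "BENIGN": (17, 95, 151)},
    # recorded for malignant pathology only
    "bilateral_yes": {"MALIGNANT": 735},
    "multifocal_yes": {"MALIGNANT": 1071},
}

TERMINAL_CATEGORY = "VI"  # first-stage category resolved without the second test


@dataclass(frozen=True)
class ReconstructionConstraints:
    """The margin system a reconstructed cohort must satisfy exactly.

    Defaults are the published counts.  ``validate`` checks the mutual
    consistency identities (equal totals across tables; the combined
    MALIGNANCY row decomposing into the terminal Bethesda VI row plus the
    FS MALIGNANCY calls among I-V; flow counts within row totals) and
    raises :class:`InfeasibilityError` naming the first violated identity.
    """

    fna_by_outcome: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_FNA_BY_OUTCOME))
    fs_by_outcome: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_FS_BY_OUTCOME))
    combined_by_outcome: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_COMBINED_BY_OUTCOME))
    malignancy_flows: dict[str, int] = field(
        default_factory=lambda: dict(_MALIGNANCY_FLOWS))
    benign_or_indet_by_fna: dict[str, int] = field(
        default_factory=lambda: dict(_BENIGN_OR_INDET_BY_FNA))

    @property
    def n(self) -> int:
        return sum(m + b for m, b in self.fna_by_outcome.values())

    def _fail(self, identity: str) -> None:
        raise InfeasibilityError(f"inconsistent constraints: {identity}")

    def fs_among_deferred(self) -> dict[str, tuple[int, int]]:
        """FS x outcome among Bethesda I-V, implied by combined minus VI."""
        vi = self.fna_by_outcome[TERMINAL_CATEGORY]
        out = {}
        for cat, (m, b) in self.combined_by_outcome.items():
            if cat == "MALIGNANCY":
                out[cat] = (m - vi[0], b - vi[1])
            else:
                out[cat] = (m, b)
        return out

    def fs_among_terminal(self) -> dict[str, tuple[int, int]]:
        """FS x outcome among Bethesda VI = total FS minus the deferred part."""
        deferred = self.fs_among_deferred()
        return {cat: (m - deferred[cat][0], b - deferred[cat][1])
                for cat, (m, b) in self.fs_by_outcome.items()}

    def validate(self) -> None:
        for axis, table in (("FNA", self.fna_by_outcome),
                            ("FS", self.fs_by_outcome),
                            ("combined", self.combined_by_outcome)):
            for cat, (m, b) in table.items():
                if m < 0 or b < 0:
                    self._fail(f"negative count in {axis} row {cat}")
        totals = {axis: (sum(m for m, _ in t.values()), sum(b for _, b in t.values()))
                  for axis, t in (("FNA", self.fna_by_outcome),
                                  ("FS", self.fs_by_outcome),
                                  ("combined", self.combined_by_outcome))}
        if len(set(totals.values())) != 1:
            self._fail(f"outcome totals differ across tables: {totals}")

        deferred = self.fs_among_deferred()
        for cat, (m, b) in deferred.items():
            if m < 0 or b < 0:
                self._fail(
                    f"combined row {cat} smaller than its terminal-VI part "
                    f"(implied FS-{cat} among I-V = ({m}, {b}))")
        among_vi = self.fs_among_terminal()
        for cat, (m, b) in among_vi.items():
            if m < 0 or b < 0:
                self._fail(
                    f"FS row {cat} smaller than its deferred (I-V) part")
        n_vi = sum(m + b for m, b in among_vi.values())
        if n_vi != sum(self.fna_by_outcome[TERMINAL_CATEGORY]):
            self._fail(
                f"FS calls among Bethesda VI sum to {n_vi}, but the VI row "
                f"total is {sum(self.fna_by_outcome[TERMINAL_CATEGORY])}")

        flow_vi = self.malignancy_flows.get(TERMINAL_CATEGORY)
        implied_vi = sum(among_vi["MALIGNANCY"])
        if flow_vi is not None and flow_vi != implied_vi:
            self._fail(
                f"printed VI->MALIGNANCY flow {flow_vi} != implied {implied_vi}")
        boi_vi = self.benign_or_indet_by_fna.get(TERMINAL_CATEGORY)
        implied_boi = sum(among_vi["BENIGN"]) + sum(among_vi["INDETERMINATE"])
        if boi_vi is not None and boi_vi != implied_boi:
            self._fail(
                f"benign/indeterminate FS among VI {boi_vi} != implied {implied_boi}")

        rest = [c for c in vocab.FNA_CATEGORIES if c != TERMINAL_CATEGORY]
        boi_rest = sum(self.benign_or_indet_by_fna[c] for c in rest)
        if boi_rest != sum(deferred["BENIGN"]) + sum(deferred["INDETERMINATE"]):
            self._fail(
                "per-category benign/indeterminate flows do not sum to the "
                "FS benign+indeterminate total among I-V")
        for cat in rest:
            row_total = sum(self.fna_by_outcome[cat])
            floor = self.benign_or_indet_by_fna[cat] \
                + self.malignancy_flows.get(cat, 0)
            if floor > row_total:
                self._fail(f"flows out of Bethesda {cat} exceed its row total")
        known = sum(v for c, v in self.malignancy_flows.items() if c != TERMINAL_CATEGORY)
        if known > sum(deferred["MALIGNANCY"]):
            self._fail(
                "printed FS-MALIGNANCY flows among I-V exceed the implied column total")


# ---------------------------------------------------------------------------
# deterministic integer allocation helpers
# ---------------------------------------------------------------------------

def largest_remainder(total: int, weights: list[float],
                      caps: list[int] | None = None) -> list[int]:
    """Split ``total`` over bins proportionally to ``weights``.

    Hamilton (largest-remainder) rounding; optional per-bin caps are
    respected by clamping and re-allocating the overflow over the
    remaining slack.  Deterministic: ties break toward earlier bins.
    """
    k = len(weights)
    if caps is None:
        caps = [total] * k
    if total > sum(caps):
        raise InfeasibilityError(
            f"cannot allocate {total} under caps summing to {sum(caps)}")
    alloc = [0] * k
    remaining = total
    active = [i for i in range(k) if caps[i] > 0]
    while remaining > 0 and active:
        wsum = sum(weights[i] for i in active)
        if wsum <= 0:
            # no weight left: fill by cap order
            for i in active:
                take = min(remaining, caps[i] - alloc[i])
                alloc[i] += take
                remaining -= take
                if remaining == 0:
                    break
            break
        quotas = {i: remaining * weights[i] / wsum for i in active}
        base = {i: min(int(quotas[i]), caps[i] - alloc[i]) for i in active}
        give = sum(base.values())
        rema = sorted(active,
                      key=lambda i: (-(quotas[i] - int(quotas[i])), i))
        for i in active:
            alloc[i] += base[i]
        remaining -= give
        for i in rema:
            if remaining == 0:
                break
            if alloc[i] < caps[i]:
                alloc[i] += 1
                remaining -= 1
        # clamp-and-retry loop: drop saturated bins
        active = [i for i in active if alloc[i] < caps[i]]
    if remaining > 0:
        raise InfeasibilityError("allocation did not converge under caps")
    return alloc


def _transportation_fill(row_sums: list[int], col_sums: list[int],
                         caps: np.ndarray, what: str) -> np.ndarray:
    """Nonnegative integer matrix with given margins and per-cell caps.

    Solved as an integer max-flow (source -> rows -> columns -> sink);
    deterministic for the fixed node ordering.  Raises
    :class:`InfeasibilityError` if the margins cannot be met.
    """
    if sum(row_sums) != sum(col_sums):
        raise InfeasibilityError(f"{what}: row and column sums differ")
    g = nx.DiGraph()
    for i, r in enumerate(row_sums):
        g.add_edge("s", ("r", i), capacity=int(r))
    for j, c in enumerate(col_sums):
        g.add_edge(("c", j), "t", capacity=int(c))
    for i in range(len(row_sums)):
        for j in range(len(col_sums)):
            if caps[i, j] > 0:
                g.add_edge(("r", i), ("c", j), capacity=int(caps[i, j]))
    value, flow = nx.maximum_flow(g, "s", "t", flow_func=edmonds_karp)
    if value != sum(row_sums):
        raise InfeasibilityError(
            f"{what}: margins infeasible under the cell caps "
            f"(max transportable {value} of {sum(row_sums)})")
    out = np.zeros_like(caps)
    for i in range(len(row_sums)):
        for j in range(len(col_sums)):
            out[i, j] = flow.get(("r", i), {}).get(("c", j), 0)
    return out


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _flow_matrix(c: ReconstructionConstraints) -> dict[str, dict[str, int]]:
    """FNA x FS patient counts satisfying every printed flow constraint.

    Forced cells first; the residual FS-MALIGNANCY flow is spread over the
    Bethesda rows without a printed count proportionally to each row's
    unallocated slack, capped by the row's malignant-outcome count (an
    FS-MALIGNANCY call with zero benign outcomes can only be filled by
    malignant patients); FS-SUSPICIOUS takes the remaining slack, and the
    scarce INDETERMINATE calls are spread over the benign-or-indeterminate
    blocks the same way.
    """
    rest = [cat for cat in vocab.FNA_CATEGORIES if cat != TERMINAL_CATEGORY]
    deferred = c.fs_among_deferred()
    among_vi = c.fs_among_terminal()

    n_flow: dict[str, dict[str, int]] = {
        TERMINAL_CATEGORY: {fs: sum(among_vi[fs]) for fs in vocab.FS_CATEGORIES}
    }
    mal_col_all_malignant = deferred["MALIGNANCY"][1] == 0

    slack, caps, unforced = {}, {}, []
    for cat in rest:
        total = sum(c.fna_by_outcome[cat])
        boi = c.benign_or_indet_by_fna[cat]
        if cat in c.malignancy_flows:
            mal = c.malignancy_flows[cat]
            susp = total - boi - mal
            if susp < 0:
                raise InfeasibilityError(
                    f"flows out of Bethesda {cat} exceed its row total")
            n_flow[cat] = {"MALIGNANCY": mal, "SUSPICIOUS": susp}
        else:
            unforced.append(cat)
            slack[cat] = total - boi
            cap = slack[cat]
            if mal_col_all_malignant:
                cap = min(cap, c.fna_by_outcome[cat][0])
            caps[cat] = cap

    residual_mal = sum(deferred["MALIGNANCY"]) - sum(
        v for k, v in c.malignancy_flows.items() if k != TERMINAL_CATEGORY)
    if unforced:
        alloc = largest_remainder(residual_mal,
                                  [slack[cat] for cat in unforced],
                                  [caps[cat] for cat in unforced])
        for cat, mal in zip(unforced, alloc):
            n_flow[cat] = {"MALIGNANCY": mal, "SUSPICIOUS": slack[cat] - mal}
    elif residual_mal != 0:
        raise InfeasibilityError(
            "every Bethesda row has a printed FS-MALIGNANCY flow but they "
            "do not sum to the implied column total")

    # split benign-or-indeterminate blocks into BENIGN / INDETERMINATE
    indet_rest = sum(deferred["INDETERMINATE"])
    boi = [c.benign_or_indet_by_fna[cat] for cat in rest]
    indet_alloc = largest_remainder(indet_rest, [float(x) for x in boi], boi)
    for cat, block, ind in zip(rest, boi, indet_alloc):
        n_flow[cat]["INDETERMINATE"] = ind
        n_flow[cat]["BENIGN"] = block - ind
    return n_flow


def reconstruct_paper_cohort(
        constraints: ReconstructionConstraints | None = None,
        include_covariates: bool = True,
        label: str = "reconstruction") -> Cohort:
    """Deterministically build a patient-level cohort matching the margins.

    The result has exactly ``constraints.n`` records (3807 by default)
    whose FNA x outcome, FS x outcome and staged-combined x outcome tables
    reproduce the constraint tables cell for cell.  Records are emitted in
    fixed vocabulary order with sequential ids, so two builds are
    identical.  Covariates (age, sex, diameter, bilaterality,
    multifocality) follow the published outcome-conditional margins via an
    even deterministic spread; pass ``include_covariates=False`` for the
    bare three-way classification.
    """
    c = constraints if constraints is not None else ReconstructionConstraints()
    c.validate()
    rest = [cat for cat in vocab.FNA_CATEGORIES if cat != TERMINAL_CATEGORY]
    n_flow = _flow_matrix(c)
    among_vi = c.fs_among_terminal()
    deferred = c.fs_among_deferred()

    # malignant count per (FNA, FS) cell; benign = cell total - malignant
    mal = {TERMINAL_CATEGORY: {fs: among_vi[fs][0] for fs in vocab.FS_CATEGORIES}}
    row_sums = [c.fna_by_outcome[cat][0] for cat in rest]
    col_sums = [deferred[fs][0] for fs in vocab.FS_CATEGORIES]
    caps = np.array([[n_flow[cat][fs] for fs in vocab.FS_CATEGORIES]
                     for cat in rest], dtype=np.int64)
    # benign margins must be transportable too: benign cell = cap - malignant
    benign_caps_ok = _transportation_fill(
        row_sums, col_sums, caps, "malignant outcome fill among Bethesda I-V")
    for i, cat in enumerate(rest):
        mal[cat] = {fs: int(benign_caps_ok[i, j])
                    for j, fs in enumerate(vocab.FS_CATEGORIES)}
    # verify the complementary benign margins (guaranteed by arithmetic,
    # but cheap to assert against a subtle constraint bug)
    for j, fs in enumerate(vocab.FS_CATEGORIES):
        ben = sum(n_flow[cat][fs] - mal[cat][fs] for cat in rest)
        if ben != deferred[fs][1]:
            raise InfeasibilityError(
                f"benign margin for FS {fs} not met after outcome fill")

    records: list[PatientRecord] = []
    serial = 0
    for cat in vocab.FNA_CATEGORIES:
        for fs in vocab.FS_CATEGORIES:
            cell = n_flow[cat][fs]
            m = mal[cat][fs]
            for outcome, count in (("MALIGNANT", m), ("BENIGN", cell - m)):
                for _ in range(count):
                    serial += 1
                    records.append(PatientRecord(
                        patient_id=f"P{serial:04d}", fna_category=cat,
                        fs_category=fs, outcome=outcome))
    if include_covariates:
        records = _attach_covariates(records)
    return Cohort(records=records, label=label)


def _spread(k: int, count: int, n: int) -> bool:
    """Bresenham-even membership: True for ``count`` of ``n`` positions."""
    return (k + 1) * count // n > k * count // n


def _attach_covariates(records: list[PatientRecord]) -> list[PatientRecord]:
    """Attach covariates matching the outcome-conditional published margins.

    Each covariate is spread evenly (deterministically) through its outcome
    stratum, so strata counts are exact while avoiding block artefacts.
    Bilaterality/multifocality are recorded for malignant pathology only,
    mirroring the source tables; benign records carry no value.
    """
    from dataclasses import replace

    by_outcome: dict[str, list[int]] = {"MALIGNANT": [], "BENIGN": []}
    for idx, rec in enumerate(records):
        by_outcome[rec.outcome].append(idx)

    out = list(records)
    for outcome, indices in by_outcome.items():
        n = len(indices)
        if n == 0:
            continue
        n_young = _COVARIATES["age_lt55"][outcome]
        n_female = _COVARIATES["sex_female"][outcome]
        d_small, d_mid, d_large = _COVARIATES["diameter"][outcome]
        n_bilat = _COVARIATES["bilateral_yes"].get(outcome)
        n_multi = _COVARIATES["multifocal_yes"].get(outcome)
        for k, idx in enumerate(indices):
            young = _spread(k, n_young, n)
            age = 30 + (k % 25) if young else 55 + (k % 20)
            female = _spread(k, n_female, n)
            # diameter stratum by cumulative even spread
            pos_small = (k + 1) * d_small // n > k * d_small // n
            pos_mid = (k + 1) * (d_small + d_mid) // n > k * (d_small + d_mid) // n
            if pos_small:
                diam = 3.0 + (k % 20) * 0.1
            elif pos_mid:
                diam = 5.0 + (k % 50) * 0.1
            else:
                diam = 10.0 + (k % 100) * 0.1
            bilat = _spread(k, n_bilat, n) if n_bilat is not None else None
            multi = _spread(k, n_multi, n) if n_multi is not None else None
            out[idx] = replace(out[idx], age_years=age,
                               sex="F" if female else "M",
                               diameter_mm=round(diam, 1),
                               bilateral=bilat, multifocal=multi)
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _check_vector(name: str, vec, length: int) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (length,):
        raise ConfigError(f"{name}: expected {length} probabilities")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > _PROB_TOL:
        raise ConfigError(f"{name}: probabilities must be >=0 and sum to 1")
    return arr


@dataclass
class SimulationConfig:
    """Categorical generative model for independent patient records.

    ``fna_given_outcome`` maps outcome -> probability vector over the six
    Bethesda categories (order VI..I, the display order);
    ``fs_given_outcome_and_fna`` maps (outcome, FNA category) -> vector
    over the four FS categories, with ``fs_given_outcome`` as the fallback
    when a pair is missing (or when collapsing to outcome-only
    conditioning).  Defaults (:meth:`paper_defaults`) are the empirical
    frequencies of the deterministic reconstruction.
    """

    n: int
    prevalence: float
    fna_given_outcome: dict[str, np.ndarray]
    fs_given_outcome: dict[str, np.ndarray]
    fs_given_outcome_and_fna: dict[tuple[str, str], np.ndarray] = field(
        default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("prevalence must be in [0, 1]")
        for outcome in vocab.OUTCOMES:
            if outcome not in self.fna_given_outcome:
                raise ConfigError(f"fna_given_outcome missing {outcome}")
            self.fna_given_outcome[outcome] = _check_vector(
                f"fna_given_outcome[{outcome}]",
                self.fna_given_outcome[outcome], len(vocab.FNA_CATEGORIES))
            if outcome not in self.fs_given_outcome:
                raise ConfigError(f"fs_given_outcome missing {outcome}")
            self.fs_given_outcome[outcome] = _check_vector(
                f"fs_given_outcome[{outcome}]",
                self.fs_given_outcome[outcome], len(vocab.FS_CATEGORIES))
        for key, vec in self.fs_given_outcome_and_fna.items():
            self.fs_given_outcome_and_fna[key] = _check_vector(
                f"fs_given_outcome_and_fna[{key}]", vec,
                len(vocab.FS_CATEGORIES))

    @classmethod
    def paper_defaults(cls, n: int = 3807, seed: int = 0,
                       collapse_fs: bool = False) -> "SimulationConfig":
        """Empirical frequencies of the deterministic reconstruction."""
        cohort = reconstruct_paper_cohort(include_covariates=False)
        config = recover_parameters(cohort)
        config.n = n
        config.seed = seed
        if collapse_fs:
            config.fs_given_outcome_and_fna = {}
        return config


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw ``config.n`` independent records; reproducible for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    outcomes = np.where(rng.random(n) < config.prevalence, "MALIGNANT", "BENIGN")
    fna = np.empty(n, dtype=object)
    fs = np.empty(n, dtype=object)
    fna_labels = np.array(vocab.FNA_CATEGORIES, dtype=object)
    fs_labels = np.array(vocab.FS_CATEGORIES, dtype=object)
    for outcome in vocab.OUTCOMES:
        mask = outcomes == outcome
        k = int(mask.sum())
        if k == 0:
            continue
        fna[mask] = fna_labels[
            rng.choice(len(fna_labels), size=k, p=config.fna_given_outcome[outcome])]
    for outcome in vocab.OUTCOMES:
        for cat in vocab.FNA_CATEGORIES:
            mask = (outcomes == outcome) & (fna == cat)
            k = int(mask.sum())
            if k == 0:
                continue
            p = config.fs_given_outcome_and_fna.get(
                (outcome, cat), config.fs_given_outcome[outcome])
            fs[mask] = fs_labels[rng.choice(len(fs_labels), size=k, p=p)]
    records = [
        PatientRecord(patient_id=f"S{i + 1:06d}", fna_category=fna[i],
                      fs_category=fs[i], outcome=outcomes[i])
        for i in range(n)
    ]
    return Cohort(records=records, label=f"simulated(seed={config.seed})")


def recover_parameters(cohort: Cohort) -> SimulationConfig:
    """Empirical prevalence and conditional category frequencies of a cohort."""
    n = len(cohort)
    if n == 0:
        raise ConfigError("cohort is empty")
    n_events = cohort.n_events
    fna_ix = {c: i for i, c in enumerate(vocab.FNA_CATEGORIES)}
    fs_ix = {c: i for i, c in enumerate(vocab.FS_CATEGORIES)}
    fna_counts = {o: np.zeros(len(vocab.FNA_CATEGORIES)) for o in vocab.OUTCOMES}
    fs_counts = {o: np.zeros(len(vocab.FS_CATEGORIES)) for o in vocab.OUTCOMES}
    pair_counts: dict[tuple[str, str], np.ndarray] = {}
    for rec in cohort:
        fna_counts[rec.outcome][fna_ix[rec.fna_category]] += 1
        fs_counts[rec.outcome][fs_ix[rec.fs_category]] += 1
        key = (rec.outcome, rec.fna_category)
        if key not in pair_counts:
            pair_counts[key] = np.zeros(len(vocab.FS_CATEGORIES))
        pair_counts[key][fs_ix[rec.fs_category]] += 1

    def _norm(vec: np.ndarray) -> np.ndarray:
        s = vec.sum()
        return vec / s if s > 0 else np.full_like(vec, 1.0 / len(vec))

    return SimulationConfig(
        n=n, prevalence=n_events / n,
        fna_given_outcome={o: _norm(v) for o, v in fna_counts.items()},
        fs_given_outcome={o: _norm(v) for o, v in fs_counts.items()},
        fs_given_outcome_and_fna={k: _norm(v) for k, v in pair_counts.items()},
        seed=0,
    )


def paper_contingency_fna() -> ContingencyTable:
    """The published FNA x outcome table as a ContingencyTable (convenience)."""
    counts = np.array([_FNA_BY_OUTCOME[c] for c in vocab.FNA_CATEGORIES])
    return ContingencyTable(row_labels=vocab.FNA_CATEGORIES, counts=counts,
                            source="published:FNA")
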