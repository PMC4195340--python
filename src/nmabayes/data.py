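"""Arm-level binomial NMA data: loading, validation, correction, restructuring.

The canonical on-disk representation is a long CSV with columns
``study, treatment, events, n`` (one row per trial arm).  A wide layout —
one row per study with an ``(events, n)`` column pair per treatment — is
accepted as an equivalent input.  Treatments are registered with 1-based
indices; treatment 1 is the reference against which the basic parameters
of the models are expressed.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx

from ._exceptions import DataError, DisconnectedNetworkError

MAX_TREATMENTS = 15
MAX_STUDIES = 50


@dataclass(frozen=True)
class Arm:
    """One treatment arm: event count out of a sample size.

    Counts are real-valued so that continuity-corrected (fractional)
    data remain representable; raw input must be integral.
    """

    treatment: int  # 1-based treatment index
    events: float
    size: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise DataError(f"arm size must be positive, got {self.size}")
        if not (0 <= self.events <= self.size):
            raise DataError(
                f"events must satisfy 0 <= events <= size, got "
                f"{self.events}/{self.size}"
            )


@dataclass(frozen=True)
class Study:
    """A randomized trial contributing >= 2 arms.

    Arms are stored baseline-first: the baseline arm is the one whose
    treatment has the lowest index, and the remaining arms follow in
    ascending treatment index.
    """

    label: str
    arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise DataError(f"single-arm study: {self.label!r}")
        treatments = [a.treatment for a in self.arms]
        if len(set(treatments)) != len(treatments):
            raise DataError(f"duplicate treatment within study {self.label!r}")
        if list(treatments) != sorted(treatments):
            object.__setattr__(
                self, "arms", tuple(sorted(self.arms, key=lambda a: a.treatment))
            )

    @property
    def baseline_treatment(self) -> int:
        return self.arms[0].treatment

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def has_zero_or_all_event_cell(self) -> bool:
        return any(a.events == 0 or a.events == a.size for a in self.arms)

    def all_arms_zero(self) -> bool:
        return all(a.events == 0 for a in self.arms)


@dataclass(frozen=True)
class DatasetSummary:
    """Totals of the evidence base (the live counts of a data-entry sheet)."""

    n_studies: int
    n_treatments: int
    n_patients: float
    n_events: float
    n_studies_with_reference: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass(frozen=True)
class EvidenceNetwork:
    """Treatments as nodes, pairwise comparisons as edges.

    ``nodes`` maps treatment index -> cumulative randomized participants;
    ``edges`` maps an ordered pair ``(i, j)`` with ``i < j`` -> number of
    trials containing both treatments.
    """

    nodes: dict[int, float]
    edges: dict[tuple[int, int], int]
    labels: dict[int, str]

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return nx.is_connected(g) if len(g) > 0 else False

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {"treatment": t, "label": self.labels[t], "participants": w}
                for t, w in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "pair": [self.labels[i], self.labels[j]],
                    "trials": w,
                }
                for (i, j), w in sorted(self.edges.items())
            ],
        }
        return json.dumps(payload, sort_keys=True)


@dataclass(frozen=True)
class NMADataset:
    """A validated collection of studies over a treatment registry.

    ``treatments`` holds the labels in registry order (index 1..K);
    ``reference`` is the 1-based index of the reference treatment
    (always 1 after :func:`set_reference` relabelling).
    """

    studies: tuple[Study, ...]
    treatments: tuple[str, ...]
    reference: int = 1
    corrected: bool = False
    warnings_: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        k = len(self.treatments)
        used = {a.treatment for s in self.studies for a in s.arms}
        if not used.issubset(set(range(1, k + 1))):
            raise DataError("arm references a treatment outside the registry")
        if used != set(range(1, k + 1)):
            missing = sorted(set(range(1, k + 1)) - used)
            raise DataError(f"treatments never used in any study: {missing}")
        labels = [s.label for s in self.studies]
        if len(set(labels)) != len(labels):
            raise DataError("duplicate study labels")
        if not (1 <= self.reference <= k):
            raise DataError(f"reference treatment {self.reference} out of range")
        net = build_network(self, _validate=False)
        if not net.is_connected():
            raise DisconnectedNetworkError(
                "disconnected network: some treatments share no path of trials"
            )
        msgs = list(self.warnings_)
        caps = []
        if k > MAX_TREATMENTS:
            caps.append(f"{k} treatments exceeds the conventional cap of "
                        f"{MAX_TREATMENTS}")
        if len(self.studies) > MAX_STUDIES:
            caps.append(f"{len(self.studies)} studies exceeds the conventional "
                        f"cap of {MAX_STUDIES}")
        for m in caps:
            if m not in msgs:
                msgs.append(m)
                warnings.warn(m, stacklevel=2)
        object.__setattr__(self, "warnings_", tuple(msgs))

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def label(self, treatment: int) -> str:
        return self.treatments[treatment - 1]

    def treatment_index(self, label: str) -> int:
        try:
            return self.treatments.index(label) + 1
        except ValueError:
            raise DataError(f"unknown treatment {label!r}") from None


@dataclass(frozen=True)
class ModelArrays:
    """Rectangular per-study arrays in the layout the samplers consume.

    Per study: treatment indices (baseline first, then ascending), event
    counts, sizes and arm count.  ``arm_labels`` flattens the data points
    in study-major order as ``(study label, treatment label)`` pairs so
    every fitted value and deviance contribution can be traced back.
    """

    t: tuple[tuple[int, ...], ...]
    r: tuple[tuple[float, ...], ...]
    n: tuple[tuple[float, ...], ...]
    na: tuple[int, ...]
    study_labels: tuple[str, ...]
    treatment_labels: tuple[str, ...]
    corrected: bool = False

    @property
    def n_studies(self) -> int:
        return len(self.na)

    @property
    def n_treatments(self) -> int:
        return len(self.treatment_labels)

    @property
    def n_datapoints(self) -> int:
        return sum(self.na)

    @property
    def arm_labels(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (self.study_labels[i], self.treatment_labels[t - 1])
            for i in range(self.n_studies)
            for t in self.t[i]
        )


# ---------------------------------------------------------------------------
# construction & IO

def _registry_from_rows(
    rows: list[tuple[str, str, float, float]],
    treatment_order: list[str] | None,
) -> tuple[list[str], dict[str, int]]:
    order: list[str] = []
    for _, treatment, _, _ in rows:
        if treatment not in order:
            order.append(treatment)
    if treatment_order is not None:
        unknown = set(order) - set(treatment_order)
        if unknown:
            raise DataError(f"treatments missing from explicit order: {sorted(unknown)}")
        order = [t for t in treatment_order if t in order]
    return order, {t: i + 1 for i, t in enumerate(order)}


def dataset_from_rows(
    rows: list[tuple[str, str, float, float]],
    treatment_order: list[str] | None = None,
    reference: str | None = None,
) -> NMADataset:
    """Build a validated dataset from ``(study, treatment, events, n)`` rows."""
    if not rows:
        raise DataError("empty dataset")
    order, index = _registry_from_rows(rows, treatment_order)
    by_study: dict[str, list[Arm]] = {}
    seen: set[tuple[str, str]] = set()
    for study, treatment, events, n in rows:
        if (study, treatment) in seen:
            raise DataError(f"duplicate (study, treatment) pair: ({study!r}, {treatment!r})")
        seen.add((study, treatment))
        if float(events) != int(events) or float(n) != int(n):
            raise DataError(
                f"raw counts must be integers: {study!r}/{treatment!r} "
                f"has {events}/{n}"
            )
        by_study.setdefault(study, []).append(
            Arm(index[treatment], float(events), float(n))
        )
    studies = tuple(Study(label, tuple(arms)) for label, arms in by_study.items())
    ds = NMADataset(studies=studies, treatments=tuple(order))
    if reference is None:
        ref_idx = _default_reference(ds)
    else:
        ref_idx = ds.treatment_index(reference)
    return set_reference(ds, ref_idx)


def _default_reference(ds: NMADataset) -> int:
    """The treatment present in the most studies (ties -> lowest index)."""
    counts = {t: 0 for t in range(1, ds.n_treatments + 1)}
    for s in ds.studies:
        for a in s.arms:
            counts[a.treatment] += 1
    return max(counts, key=lambda t: (counts[t], -t))


def set_reference(ds: NMADataset, reference: int) -> NMADataset:
    """Relabel treatments so that ``reference`` becomes treatment 1.

    The other treatments keep their relative registry order.  Model basic
    parameters are always expressed against treatment 1, so choosing a
    reference is a pure relabelling of the dataset.
    """
    if reference == 1:
        return replace(ds, reference=1)
    if not (1 <= reference <= ds.n_treatments):
        raise DataError(f"reference treatment {reference} out of range")
    old_order = list(range(1, ds.n_treatments + 1))
    new_order = [reference] + [t for t in old_order if t != reference]
    remap = {old: new + 1 for new, old in enumerate(new_order)}
    studies = tuple(
        Study(
            s.label,
            tuple(Arm(remap[a.treatment], a.events, a.size) for a in s.arms),
        )
        for s in ds.studies
    )
    treatments = tuple(ds.treatments[t - 1] for t in new_order)
    return NMADataset(studies=studies, treatments=treatments, reference=1,
                      corrected=ds.corrected)


def load_long(path, treatment_order: list[str] | None = None,
              reference: str | None = None) -> NMADataset:
    """Load the canonical long CSV (``study,treatment,events,n``)."""
    rows: list[tuple[str, str, float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataError(f"empty file: {path}")
        needed = {"study", "treatment", "events", "n"}
        if not needed.issubset({f.strip().lower() for f in reader.fieldnames}):
            raise DataError(
                f"long CSV must have columns study,treatment,events,n; "
                f"found {reader.fieldnames}"
            )
        keymap = {f.strip().lower(): f for f in reader.fieldnames}
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (
                        row[keymap["study"]].strip(),
                        row[keymap["treatment"]].strip(),
                        float(row[keymap["events"]]),
                        float(row[keymap["n"]]),
                    )
                )
            except (TypeError, ValueError, AttributeError) as exc:
                raise DataError(f"malformed row {lineno} in {path}: {row}") from exc
    return dataset_from_rows(rows, treatment_order=treatment_order,
                             reference=reference)


def load_wide(path, reference: str | None = None) -> NMADataset:
    """Load a wide CSV: study column, then an (events, n) pair per treatment.

    The header row names each treatment above the first column of its pair
    (the second column of a pair may repeat the name or be blank).  Blank
    pairs mean the treatment was absent from that study.  The resulting
    dataset is identical to loading the equivalent long file with the
    header's treatment order.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        raw = [row for row in csv.reader(fh) if any(c.strip() for c in row)]
    if not raw:
        raise DataError(f"empty file: {path}")
    header = raw[0]
    if len(header) < 3 or (len(header) - 1) % 2 != 0:
        raise DataError(
            "wide CSV needs a study column plus an even number of "
            f"(events, n) columns; found {len(header)} columns"
        )
    treatments = [header[i].strip() for i in range(1, len(header), 2)]
    if any(not t for t in treatments):
        raise DataError("every (events, n) column pair needs a treatment name")
    rows: list[tuple[str, str, float, float]] = []
    for lineno, row in enumerate(raw[1:], start=2):
        study = row[0].strip()
        cells = list(row[1:]) + [""] * (len(header) - len(row))
        for j, treatment in enumerate(treatments):
            ev, n = cells[2 * j].strip(), cells[2 * j + 1].strip()
            if not ev and not n:
                continue
            if not ev or not n:
                raise DataError(
                    f"row {lineno} ({study!r}): half-filled pair for {treatment!r}"
                )
            try:
                rows.append((study, treatment, float(ev), float(n)))
            except ValueError as exc:
                raise DataError(f"malformed row {lineno} in {path}") from exc
    return dataset_from_rows(rows, treatment_order=treatments, reference=reference)


def write_long(ds: NMADataset, path) -> None:
    """Write the canonical long CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["study", "treatment", "events", "n"])
        for s in ds.studies:
            for a in s.arms:
                ev = int(a.events) if a.events == int(a.events) else a.events
                n = int(a.size) if a.size == int(a.size) else a.size
                writer.writerow([s.label, ds.label(a.treatment), ev, n])


# ---------------------------------------------------------------------------
# operations

def summarize(ds: NMADataset) -> DatasetSummary:
    """Totals over the evidence base; reference-study count uses ``ds.reference``."""
    n_events = sum(a.events for s in ds.studies for a in s.arms)
    n_patients = sum(a.size for s in ds.studies for a in s.arms)
    with_ref = sum(
        1 for s in ds.studies if any(a.treatment == ds.reference for a in s.arms)
    )
    def as_count(x: float):
        return int(x) if x == int(x) else x
    return DatasetSummary(
        n_studies=ds.n_studies,
        n_treatments=ds.n_treatments,
        n_patients=as_count(n_patients),
        n_events=as_count(n_events),
        n_studies_with_reference=with_ref,
    )


def build_network(ds: NMADataset, _validate: bool = True) -> EvidenceNetwork:
    """Evidence network: node weight = randomized participants, edge weight =
    number of trials containing both treatments of the pair."""
    nodes: dict[int, float] = {}
    edges: dict[tuple[int, int], int] = {}
    for s in ds.studies:
        ts = [a.treatment for a in s.arms]
        for a in s.arms:
            nodes[a.treatment] = nodes.get(a.treatment, 0) + a.size
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                pair = (min(ts[i], ts[j]), max(ts[i], ts[j]))
                edges[pair] = edges.get(pair, 0) + 1
    labels = {t: ds.treatments[t - 1] for t in nodes}
    return EvidenceNetwork(nodes=nodes, edges=edges, labels=labels)


def apply_continuity_correction(ds: NMADataset, correct: bool = True) -> NMADataset:
    """Adjusted continuity correction for studies with zero or all-event cells.

    Every arm ``a`` of an affected study gains ``c_a`` events and ``2*c_a``
    participants, where ``c_a`` is proportional to the reciprocal of the mean
    size of the *other* arms in the study and the per-study corrections are
    normalized to sum to ``n_arms / 2`` — so the correction is centered
    around 0.5 per arm and exactly 0.5 when all arm sizes are equal.
    Unaffected studies are untouched and no study is ever dropped.

    With ``correct=False`` the dataset is returned unchanged (the analyst
    declined the adjustment; zero cells enter the likelihood as-is).
    """
    if not correct:
        return ds
    new_studies: list[Study] = []
    msgs: list[str] = []
    touched = False
    for s in ds.studies:
        if not s.has_zero_or_all_event_cell():
            new_studies.append(s)
            continue
        touched = True
        if s.all_arms_zero():
            msg = (
                f"study {s.label!r} has zero events in every arm and does not "
                "contribute to the relative effect estimation"
            )
            msgs.append(msg)
            warnings.warn(msg, stacklevel=2)
        sizes = [a.size for a in s.arms]
        total = sum(sizes)
        weights = []
        for a in s.arms:
            other_mean = (total - a.size) / (len(sizes) - 1)
            weights.append(1.0 / other_mean)
        scale = (len(sizes) / 2.0) / sum(weights)
        corrected_arms = tuple(
            Arm(a.treatment, a.events + w * scale, a.size + 2 * w * scale)
            for a, w in zip(s.arms, weights)
        )
        new_studies.append(Study(s.label, corrected_arms))
    return NMADataset(
        studies=tuple(new_studies),
        treatments=ds.treatments,
        reference=ds.reference,
        corrected=ds.corrected or touched,
        warnings_=tuple(msgs),
    )


def prepare_model_arrays(ds: NMADataset) -> ModelArrays:
    """Restructure a dataset into the rectangular per-study sampler layout."""
    return ModelArrays(
        t=tuple(tuple(a.treatment for a in s.arms) for s in ds.studies),
        r=tuple(tuple(a.events for a in s.arms) for s in ds.studies),
        n=tuple(tuple(a.size for a in s.arms) for s in ds.studies),
        na=tuple(s.n_arms for s in ds.studies),
        study_labels=tuple(s.label for s in ds.studies),
        treatment_labels=ds.treatments,
        corrected=ds.corrected,
    )


def arrays_to_dataset(arrays: ModelArrays) -> NMADataset:
    """Inverse of :func:`prepare_model_arrays` (round-trip helper)."""
    studies = tuple(
        Study(
            arrays.study_labels[i],
            tuple(
                Arm(arrays.t[i][k], arrays.r[i][k], arrays.n[i][k])
                for k in range(arrays.na[i])
            ),
        )
        for i in range(arrays.n_studies)
    )
    return NMADataset(
        studies=studies,
        treatments=arrays.treatment_labels,
        reference=1,
        corrected=arrays.corrected,
    )
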