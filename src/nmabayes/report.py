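"""Posterior reporting: summaries, SUCRA ranking, league table, forest and
network-diagram data, and the exported report bundle.

League-table orientation: ``cell(row, column)`` summarizes the odds ratio
of the *row* treatment versus the *column* treatment, read top-to-bottom
then left-to-right; the convention is restated in every exported header
because league tables are notoriously ambiguous on this point.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass

import numpy as np

from .data import DatasetSummary, EvidenceNetwork
from .models import consistency_or
from .sampler import PosteriorDraws


@dataclass(frozen=True)
class PosteriorSummary:
    """Median, 95% credible interval, mean and sd of one scalar quantity."""

    parameter: str
    median: float
    lower: float
    upper: float
    mean: float
    sd: float


def summarize_posterior(
    draws: PosteriorDraws | np.ndarray, parameter: str | None = None
) -> PosteriorSummary:
    """Pooled-chain posterior summary.

    Quantiles use linear interpolation between order statistics (the
    numpy default convention; on draws 1..100 the 95% interval is
    (3.475, 97.525)).
    """
    if isinstance(draws, PosteriorDraws):
        x = draws.pooled(parameter)
        name = parameter
    else:
        x = np.asarray(draws, dtype=float)
        name = parameter or ""
    if x.size == 0:
        raise ValueError("empty draws")
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return PosteriorSummary(
        parameter=name,
        median=float(med),
        lower=float(lo),
        upper=float(hi),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# ranking

@dataclass(frozen=True)
class RankTable:
    """Rank probabilities P[treatment, rank] and SUCRA per treatment.

    Rows (over ranks) and columns (over treatments) each sum to 1.
    SUCRA = mean of the cumulative rank probabilities over ranks
    1..K-1: 1 for a certain-best treatment, 0 for a certain-worst one.
    """

    treatments: tuple[str, ...]
    probabilities: np.ndarray  # (K, K): rank r is column r-1
    sucra: np.ndarray          # (K,)

    def best_to_worst(self) -> list[int]:
        """1-based treatment indices ordered by descending SUCRA
        (ties broken by treatment index)."""
        order = sorted(
            range(len(self.treatments)), key=lambda t: (-self.sucra[t], t)
        )
        return [t + 1 for t in order]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            k = len(self.treatments)
            writer.writerow(
                ["treatment"] + [f"P(rank {r})" for r in range(1, k + 1)] + ["SUCRA"]
            )
            for t, label in enumerate(self.treatments):
                writer.writerow(
                    [label]
                    + [f"{v:.6f}" for v in self.probabilities[t]]
                    + [f"{self.sucra[t]:.6f}"]
                )


def rank_probabilities(draws: PosteriorDraws, direction: str | None = None) -> RankTable:
    """Empirical rank probabilities and SUCRA from consistency draws.

    Per draw, treatments are ordered by their basic parameter (log odds
    versus reference; the reference itself sits at 0): ascending when the
    outcome is "bad" (fewer events is better), descending when "good".
    Ties break by treatment index.
    """
    if direction is None:
        direction = draws.spec.direction
    if direction not in ("bad", "good"):
        raise ValueError(f"unknown direction {direction!r}")
    k = draws.n_treatments
    d_names = [f"d[{t}]" for t in range(2, k + 1)]
    cols = [np.zeros(draws.n_kept * draws.n_chains)]
    cols += [draws.pooled(nm) for nm in d_names]
    effects = np.column_stack(cols)
    if direction == "good":
        effects = -effects
    order = np.argsort(effects, axis=1, kind="stable")
    counts = np.zeros((k, k))
    for pos in range(k):
        idx, cnt = np.unique(order[:, pos], return_counts=True)
        counts[idx, pos] += cnt
    probs = counts / effects.shape[0]
    cum = np.cumsum(probs, axis=1)
    sucra = cum[:, : k - 1].mean(axis=1) if k > 1 else np.ones(1)
    return RankTable(
        treatments=draws.treatment_labels, probabilities=probs, sucra=sucra
    )


# ---------------------------------------------------------------------------
# league table

@dataclass(frozen=True)
class LeagueTable:
    """K x K grid: SUCRA-ordered treatment names on the diagonal, pairwise
    odds-ratio summaries (row versus column) off the diagonal."""

    order: tuple[int, ...]          # 1-based treatment indices, best first
    labels: tuple[str, ...]         # labels in diagonal order
    cells: tuple[tuple[PosteriorSummary | None, ...], ...]

    HEADER = (
        "league table: cell(row, column) is the odds ratio of the row "
        "treatment versus the column treatment; read top to bottom, left to right"
    )

    def cell(self, row: int, col: int) -> PosteriorSummary | None:
        return self.cells[row][col]

    def to_csv(self, path) -> None:
        k = len(self.order)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([self.HEADER])
            for i in range(k):
                row = []
                for j in range(k):
                    if i == j:
                        row.append(self.labels[i])
                    else:
                        c = self.cells[i][j]
                        row.append(f"{c.median:.2f} ({c.lower:.2f}-{c.upper:.2f})")
                writer.writerow(row)


def league_table(draws: PosteriorDraws, ranks: RankTable | None = None) -> LeagueTable:
    """Build the SUCRA-ordered league table from consistency draws."""
    if ranks is None:
        ranks = rank_probabilities(draws)
    order = tuple(ranks.best_to_worst())
    labels = tuple(draws.treatment_labels[t - 1] for t in order)
    k = len(order)
    cells: list[list[PosteriorSummary | None]] = [[None] * k for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            # row vs column: exp(d_row - d_col); quantiles are taken on the
            # log scale and exponentiated, so cell(i,j) * cell(j,i) = 1
            # holds exactly for the median and the swapped CrI bounds
            or_draws = consistency_or(draws, order[j], order[i])
            log_or = np.log(or_draws)
            lo, med, hi = np.exp(np.quantile(log_or, [0.025, 0.5, 0.975]))
            cells[i][j] = PosteriorSummary(
                parameter=f"OR({labels[i]} vs {labels[j]})",
                median=float(med), lower=float(lo), upper=float(hi),
                mean=float(or_draws.mean()),
                sd=float(or_draws.std(ddof=1)),
            )
    return LeagueTable(order=order, labels=labels,
                       cells=tuple(tuple(r) for r in cells))


# ---------------------------------------------------------------------------
# forest data

def forest_data(
    draws_by_model: dict[str, PosteriorDraws],
    pairs: str = "reference",
) -> list[dict]:
    """Plot-ready forest records: one per (comparison, model).

    ``pairs`` is "reference" (each treatment versus treatment 1) or "all"
    (every ordered pair i<j as j versus i).  The reference-vs-reference
    row is never emitted.
    """
    if not draws_by_model:
        raise ValueError("at least one model must be selected")
    if pairs not in ("reference", "all"):
        raise ValueError(f"unknown pairs selection {pairs!r}")
    records = []
    for model, draws in draws_by_model.items():
        k = draws.n_treatments
        labels = draws.treatment_labels
        if pairs == "reference":
            combos = [(1, j) for j in range(2, k + 1)]
        else:
            combos = [(i, j) for i in range(1, k + 1) for j in range(i + 1, k + 1)]
        for i, j in combos:
            s = summarize_posterior(consistency_or(draws, i, j))
            records.append(
                {
                    "comparison": f"{labels[j - 1]} vs {labels[i - 1]}",
                    "model": model,
                    "median": s.median,
                    "lower": s.lower,
                    "upper": s.upper,
                }
            )
    return records


# ---------------------------------------------------------------------------
# network layout

def network_layout(
    net: EvidenceNetwork,
    labels: dict[int, str] | None = None,
    max_radius: float = 0.15,
    max_width: float = 8.0,
) -> dict:
    """Circular layout with area-proportional nodes.

    Node radius scales with sqrt(participants) (area proportional to the
    randomized sample size); edge width scales linearly with the number
    of trials of the comparison.  ``labels`` overrides node labels.
    """
    treatments = sorted(net.nodes)
    k = len(treatments)
    wmax = max(net.nodes.values())
    emax = max(net.edges.values()) if net.edges else 1
    nodes = []
    for pos, t in enumerate(treatments):
        angle = math.pi / 2 - 2 * math.pi * pos / k
        nodes.append(
            {
                "treatment": t,
                "label": (labels or {}).get(t, net.labels[t]),
                "x": math.cos(angle),
                "y": math.sin(angle),
                "radius": max_radius * math.sqrt(net.nodes[t] / wmax),
                "participants": net.nodes[t],
            }
        )
    edges = [
        {
            "pair": [i, j],
            "trials": w,
            "width": max_width * w / emax,
        }
        for (i, j), w in sorted(net.edges.items())
    ]
    return {"nodes": nodes, "edges": edges}


# ---------------------------------------------------------------------------
# report bundle

def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in obj.__dict__.items() if not k.startswith("_")}
    raise TypeError(f"not JSON serializable: {type(obj)}")


def export_report(
    outdir,
    *,
    dataset_summary: DatasetSummary | None = None,
    network: EvidenceNetwork | None = None,
    models: dict[str, dict] | None = None,
    devdev: list[dict] | None = None,
    figures: bool = False,
) -> str:
    """Write the analysis bundle (JSON + CSV tables, optional figures).

    ``models`` maps a model name to a dict that may hold ``summaries``
    (list of PosteriorSummary), ``league`` (LeagueTable), ``ranks``
    (RankTable), ``convergence`` (ConvergenceReport), ``fit``
    (FitStatistics) and ``forest`` (forest records).  Returns the path of
    the master ``report.json``, which is byte-stable for unchanged inputs
    (sorted keys, plain-float formatting).
    """
    os.makedirs(outdir, exist_ok=True)
    report: dict = {}
    if dataset_summary is not None:
        report["dataset_summary"] = dataset_summary.__dict__
    if network is not None:
        report["network"] = json.loads(network.to_json())
        with open(os.path.join(outdir, "network.json"), "w", encoding="utf-8") as fh:
            fh.write(network.to_json())
    report["models"] = {}
    for name, parts in (models or {}).items():
        entry: dict = {}
        if "summaries" in parts:
            entry["summaries"] = [s.__dict__ for s in parts["summaries"]]
        if "league" in parts:
            league: LeagueTable = parts["league"]
            league.to_csv(os.path.join(outdir, f"league_{name}.csv"))
            entry["league"] = {
                "convention": LeagueTable.HEADER,
                "diagonal": list(league.labels),
                "cells": [
                    [None if c is None else c.__dict__ for c in row]
                    for row in league.cells
                ],
            }
        if "ranks" in parts:
            ranks: RankTable = parts["ranks"]
            ranks.to_csv(os.path.join(outdir, f"ranks_{name}.csv"))
            entry["ranks"] = {
                "treatments": list(ranks.treatments),
                "probabilities": ranks.probabilities.tolist(),
                "sucra": ranks.sucra.tolist(),
            }
        if "convergence" in parts:
            entry["convergence"] = json.loads(parts["convergence"].to_json())
        if "fit" in parts:
            entry["fit"] = json.loads(parts["fit"].to_json())
        if "forest" in parts:
            entry["forest"] = parts["forest"]
        report["models"][name] = entry
    if devdev is not None:
        from .diagnostics import write_devdev_csv

        write_devdev_csv(devdev, os.path.join(outdir, "devdev.csv"))
        report["devdev"] = devdev
    path = os.path.join(outdir, "report.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")
    if figures:
        _render_figures(outdir, network=network, models=models or {})
    return path


def _render_figures(outdir, network, models) -> None:
    """Optional SVG rendering of the network diagram and forest plots."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if network is not None:
        layout = network_layout(network)
        fig, ax = plt.subplots(figsize=(5, 5))
        pos = {n["treatment"]: (n["x"], n["y"]) for n in layout["nodes"]}
        for e in layout["edges"]:
            i, j = e["pair"]
            ax.plot(*zip(pos[i], pos[j]), lw=e["width"], color="0.6", zorder=1)
        for node in layout["nodes"]:
            ax.add_patch(
                plt.Circle((node["x"], node["y"]), node["radius"], zorder=2)
            )
            ax.annotate(node["label"], (node["x"], node["y"]),
                        ha="center", va="bottom",
                        xytext=(0, 12), textcoords="offset points")
        ax.set_xlim(-1.4, 1.4)
        ax.set_ylim(-1.4, 1.4)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.savefig(os.path.join(outdir, "network.svg"))
        plt.close(fig)
    for name, parts in models.items():
        if "forest" not in parts:
            continue
        recs = parts["forest"]
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(recs) + 1.5))
        ys = range(len(recs), 0, -1)
        for y, rec in zip(ys, recs):
            ax.plot([rec["lower"], rec["upper"]], [y, y], color="k")
            ax.plot(rec["median"], y, "s", color="k")
        ax.axvline(1.0, color="0.5", ls="--", lw=0.8)
        ax.set_yticks(list(ys))
        ax.set_yticklabels([r["comparison"] for r in recs])
        ax.set_xscale("log")
        ax.set_xlabel("odds ratio (95% CrI)")
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, f"forest_{name}.svg"))
        plt.close(fig)
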