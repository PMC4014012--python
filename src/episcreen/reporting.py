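"""Screen summary artifacts: heatmap tables, synergy network, panels.

Everything here is a pure function of the per-(combination, trait)
records produced by the epistasis module: a heatmap table of
percentages vs expectation (pink below 100%, green above), an
undirected synergy network whose edges are the synergistic
combinations with per-gene synergy percentages, and per-combination
statistical panels. Percentages are stored at full precision and
rounded to integers only for display, matching the figures' convention.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

LEAF_TRAITS = [f"L{i}" for i in range(7)]
HEATMAP_COLUMNS = ["C/W"] + LEAF_TRAITS + ["rosette"]


def build_heatmap_table(records: pd.DataFrame) -> pd.DataFrame:
    """One row per combination: C/W plus C/E for L0..L6 and the rosette.

    Missing traits leave explicit gaps (NaN) with a warning. Rows are
    ordered canonically by combo_id, so permuted input records give an
    identical table. Flag columns carry the significance label and the
    bold (>= 5% above both controls) / strong (>= 20% above EXPni)
    markers of the rosette record.
    """
    rows = {}
    for combo, sub in records.groupby("combo_id"):
        sub = sub.set_index("trait")
        if "rosette" not in sub.index:
            warnings.warn(f"combination {combo} lacks a rosette record")
        row = {}
        row["C/W"] = sub["c_w"].get("rosette", np.nan)
        for t in LEAF_TRAITS:
            row[t] = sub["c_e"].get(t, np.nan)
        row["rosette"] = sub["c_e"].get("rosette", np.nan)
        if row["rosette"] != row["rosette"] or any(
                row[t] != row[t] for t in LEAF_TRAITS):
            warnings.warn(f"combination {combo}: incomplete trait set")
        if "rosette" in sub.index:
            ros = sub.loc["rosette"]
            row["label"] = ros["label"]
            row["bold"] = bool(ros["bold_5pct_above_both_controls"])
            row["strong"] = bool(ros["strong_20pct_above_expni"])
        else:
            row["label"], row["bold"], row["strong"] = "", False, False
        rows[combo] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "combo_id"
    return table


def render_heatmap(table: pd.DataFrame, path) -> Path:
    """Render the heatmap with a diverging scale anchored at 100%."""
    values = table[HEATMAP_COLUMNS].to_numpy(float)
    span = max(np.nanmax(np.abs(values - 100.0)), 1.0)
    fig, ax = plt.subplots(
        figsize=(0.9 * len(HEATMAP_COLUMNS) + 2, 0.3 * len(table) + 1.5))
    im = ax.imshow(values, cmap="PiYG", vmin=100 - span, vmax=100 + span,
                   aspect="auto")
    ax.set_xticks(range(len(HEATMAP_COLUMNS)), HEATMAP_COLUMNS)
    ax.set_yticks(range(len(table)),
                  [f"{c}{' *' if b else ''}" for c, b in
                   zip(table.index, table["bold"])])
    fig.colorbar(im, ax=ax, label="% of expectation (100 = as expected)")
    ax.set_title("observed size vs expected-if-non-interacting")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def build_synergy_network(records: pd.DataFrame,
                          design: pd.DataFrame) -> nx.Graph:
    """Undirected network of lines connected by synergistic combinations.

    Nodes are the parental lines of all analyzed combinations; an edge
    joins two lines whose cross is labelled synergistic at the rosette
    level. Each node carries ``synergy_pct``: 100 x (synergistic
    combinations containing the line) / (analyzed combinations
    containing it), stored at full precision (round for display).
    """
    ros = records[records["trait"] == "rosette"].set_index("combo_id")
    design = design.set_index("combo_id")
    G = nx.Graph()
    analyzed: dict[str, int] = {}
    synergistic: dict[str, int] = {}
    for combo in ros.index:
        if combo not in design.index:
            continue
        p1, p2 = design.loc[combo, "parent1"], design.loc[combo, "parent2"]
        for p in (p1, p2):
            G.add_node(p)
            analyzed[p] = analyzed.get(p, 0) + 1
        if ros.loc[combo, "label"] == "synergistic":
            G.add_edge(p1, p2, combo_id=combo,
                       c_e=float(ros.loc[combo, "c_e"]))
            for p in (p1, p2):
                synergistic[p] = synergistic.get(p, 0) + 1
    for p in G.nodes:
        G.nodes[p]["n_analyzed"] = analyzed.get(p, 0)
        G.nodes[p]["n_synergistic"] = synergistic.get(p, 0)
        G.nodes[p]["synergy_pct"] = (
            100.0 * synergistic.get(p, 0) / analyzed[p] if analyzed.get(p) else 0.0
        )
    return G


def network_to_json(G: nx.Graph, path=None) -> dict:
    """Serialise the synergy network (nodes, edges, percentages)."""
    data = {
        "nodes": [{"id": n, **G.nodes[n]} for n in sorted(G.nodes)],
        "edges": [{"source": u, "target": v, **d}
                  for u, v, d in sorted(G.edges(data=True))],
    }
    if path is not None:
        Path(path).write_text(json.dumps(data, indent=2))
    return data


def render_synergy_network(G: nx.Graph, path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 7))
    pos = nx.circular_layout(G)
    pct = [G.nodes[n]["synergy_pct"] for n in G.nodes]
    nx.draw_networkx(G, pos=pos, ax=ax, node_color=pct, cmap="Greens",
                     vmin=0, vmax=100, node_size=900, font_size=8,
                     edge_color="grey")
    ax.set_title("synergistic combinations (node colour: % synergistic)")
    ax.axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_combination_panel(records: pd.DataFrame, combo_id: str,
                             outdir) -> dict:
    """Per-combination report: percentage/FDR table plus leaf profile.

    Writes ``<combo>_panel.csv`` (P1/W, P2/W, C/W, C/E and the
    within-combination FDR per trait) and ``<combo>_panel.png`` (the
    per-leaf C/E profile with the 100% expectation line). Returns the
    paths and the table.
    """
    sub = records[records["combo_id"] == combo_id]
    if sub.empty:
        raise ValueError(f"no records for combination {combo_id!r}")
    order = [t for t in LEAF_TRAITS + ["rosette"] if t in set(sub["trait"])]
    table = (sub.set_index("trait")
             .loc[order, ["p1_w", "p2_w", "c_w", "c_e", "q_combo", "label"]]
             .rename(columns={"p1_w": "P1/W", "p2_w": "P2/W", "c_w": "C/W",
                              "c_e": "C/E", "q_combo": "FDR"}))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{combo_id}_panel.csv"
    table.to_csv(csv_path)

    fig, ax = plt.subplots(figsize=(6, 4))
    leaf_rows = table.loc[[t for t in order if t != "rosette"]]
    x = np.arange(len(leaf_rows))
    ax.axhline(100.0, color="grey", ls="--", label="EXPni (100%)")
    ax.plot(x, leaf_rows["C/E"], "o-", color="crimson", label="C/E")
    ax.plot(x, leaf_rows["C/W"], "s-", color="seagreen", label="C/W")
    ax.set_xticks(x, leaf_rows.index)
    ax.set_ylabel("% of reference")
    ax.set_title(combo_id)
    ax.legend()
    fig.tight_layout()
    png_path = outdir / f"{combo_id}_panel.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"table": table, "csv": csv_path, "figure": png_path}


def write_screen_outputs(result, design: pd.DataFrame, outdir) -> dict:
    """Write the standard artifact bundle for one screen run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    result.records.to_csv(outdir / "records.csv", index=False)
    paths["records"] = outdir / "records.csv"
    table = build_heatmap_table(result.records)
    table.to_csv(outdir / "heatmap.csv")
    paths["heatmap_csv"] = outdir / "heatmap.csv"
    paths["heatmap_png"] = render_heatmap(table, outdir / "heatmap.png")
    G = build_synergy_network(result.records, design)
    network_to_json(G, outdir / "network.json")
    paths["network_json"] = outdir / "network.json"
    paths["network_png"] = render_synergy_network(G, outdir / "network.png")
    if len(result.removed_outliers):
        result.removed_outliers.to_csv(outdir / "removed_outliers.csv",
                                       index=False)
        paths["removed_outliers"] = outdir / "removed_outliers.csv"
    return paths
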