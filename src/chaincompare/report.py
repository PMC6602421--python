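"""Comparison driver and report rendering.

:func:`run_comparison` executes the whole pipeline — parse, select, align,
superpose, assign, difference tracks, summaries — and returns a
:class:`Report`; :func:`render_text` prints it as column-aligned track
blocks, :func:`render_json` as a schema-stable JSON document carrying every
track at full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from . import difference_engine as de
from .chain_alignment import (
    PairAlignment,
    align_sequences,
    load_transform,
    superpose,
)
from .secondary_structure import (
    METHOD_LABELS,
    SSAssignment,
    assign_ca_geometry,
    assign_hbond,
    parse_assignment_file,
)
from .structure_io import (
    Chain,
    ResidueRange,
    effective_resolution,
    read_structure,
    select_chain,
)

logger = logging.getLogger("chaincompare")


@dataclass
class ComparisonConfig:
    """Everything :func:`run_comparison` needs; mirrors the CLI flags."""

    structure_a: object  # path or text
    structure_b: object
    chain_a: str = "A"
    chain_b: str = "A"
    model_a: int = 1
    model_b: int = 1
    range_a: ResidueRange | None = None
    range_b: ResidueRange | None = None
    methods: tuple[str, ...] = ("hbond",)
    dssp_a: str | None = None  # external DSSP report files
    dssp_b: str | None = None
    stride_a: str | None = None
    stride_b: str | None = None
    contact_cutoff: float = de.DEFAULT_CONTACT_CUTOFF
    neighbour_exclusion: bool = True
    include_missing_as_other: bool = True
    trim_fraction: float = 0.1
    trim_rounds: int = 2
    transform_file: str | None = None
    selection_a: ResidueRange | None = None
    selection_b: ResidueRange | None = None


@dataclass
class Report:
    """All comparison results for one chain pair."""

    header: dict
    resnum_a: list[str]
    resnum_b: list[str]
    seq_a: list[str]
    seq_b: list[str]
    ss_a: dict[str, list[str | None]]  # per-method extended states, aligned
    ss_b: dict[str, list[str | None]]
    consensus_a: list[str | None]
    consensus_b: list[str | None]
    bfactors_a: list[float | None]
    bfactors_b: list[float | None]
    differences: dict[str, list[bool | None]]  # per method + "consensus"
    ca_dist: list[float | None]
    sc_dist: list[float | None]
    contacts: list[int | None]
    summaries: dict[str, dict]

    def n_positions(self) -> int:
        return len(self.seq_a)


def _assignments(chain: Chain, cfg: ComparisonConfig, side: str) -> dict[str, SSAssignment]:
    out: dict[str, SSAssignment] = {}
    for method in cfg.methods:
        if method == "hbond":
            out[method] = assign_hbond(chain)
        elif method == "ca_geom":
            out[method] = assign_ca_geometry(chain)
        elif method == "dssp_file":
            path = cfg.dssp_a if side == "a" else cfg.dssp_b
            out[method] = parse_assignment_file(path, "dssp_file", chain)
        elif method == "stride_file":
            path = cfg.stride_a if side == "a" else cfg.stride_b
            out[method] = parse_assignment_file(path, "stride_file", chain)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not out[method].enabled:
            logger.warning("method %s produced no output for chain %s; disabled",
                           method, chain.chain_id)
    return out


def _aligned(values, alignment: PairAlignment, side: str):
    k = 0 if side == "a" else 1
    return [None if p[k] is None else values[p[k]] for p in alignment.pairs]


def _selection_indices(chain: Chain, rng: ResidueRange | None):
    if rng is None:
        return None
    idx = {r.seq_index for r in chain.residues if r.author_number in rng}
    return idx or None


def run_comparison(cfg: ComparisonConfig) -> Report:
    """Execute the full comparison pipeline; deterministic given inputs."""
    chains_a = read_structure(cfg.structure_a)
    chains_b = read_structure(cfg.structure_b)
    a = select_chain(chains_a, cfg.model_a, cfg.chain_a, cfg.range_a)
    b = select_chain(chains_b, cfg.model_b, cfg.chain_b, cfg.range_b)

    alignment = align_sequences(a, b)
    external = load_transform(cfg.transform_file) if cfg.transform_file else None
    sup = superpose(
        a, b, alignment,
        trim_fraction=cfg.trim_fraction,
        trim_rounds=cfg.trim_rounds,
        external=external,
    )

    asg_a = _assignments(a, cfg, "a")
    asg_b = _assignments(b, cfg, "b")
    # a method disabled for either chain is dropped for both
    usable = [m for m in cfg.methods if asg_a[m].enabled and asg_b[m].enabled]
    if not usable:
        raise de.NoMethodError("every requested method is disabled on at least one chain")
    cons_a = de.consensus([asg_a[m] for m in usable])
    cons_b = de.consensus([asg_b[m] for m in usable])

    differences: dict[str, list[bool | None]] = {}
    for m in usable:
        differences[m] = de.differences_line(
            _aligned(asg_a[m].extended, alignment, "a"),
            _aligned(asg_b[m].extended, alignment, "b"),
        )
    differences["consensus"] = de.differences_line(
        _aligned(cons_a.states, alignment, "a"),
        _aligned(cons_b.states, alignment, "b"),
    )

    pct_a = de.bfactor_percentiles(a)
    pct_b = de.bfactor_percentiles(b)

    summaries = {}
    for label, chain, cons in (("whole_chain_a", a, cons_a), ("whole_chain_b", b, cons_b)):
        s = de.summarize(chain, cons, sup,
                         include_missing_as_other=cfg.include_missing_as_other)
        summaries[label] = s.__dict__
    for label, chain, cons, rng in (
        ("selection_a", a, cons_a, cfg.selection_a),
        ("selection_b", b, cons_b, cfg.selection_b),
    ):
        idx = _selection_indices(chain, rng)
        if idx:
            summaries[label] = de.summarize(
                chain, cons, sup, selection=idx,
                include_missing_as_other=cfg.include_missing_as_other,
            ).__dict__

    header = {
        "chain_a": {
            "source": a.source, "chain": a.chain_id, "model": a.model_id,
            "n_residues": len(a), "effective_resolution": effective_resolution(a),
            "range": [cfg.range_a.start, cfg.range_a.end] if cfg.range_a else None,
        },
        "chain_b": {
            "source": b.source, "chain": b.chain_id, "model": b.model_id,
            "n_residues": len(b), "effective_resolution": effective_resolution(b),
            "range": [cfg.range_b.start, cfg.range_b.end] if cfg.range_b else None,
        },
        "methods": list(usable),
        "identity": alignment.identity,
        "rmsd": sup.rmsd,
        "rmsd_all_pairs": sup.rmsd_all,
        "n_fitted": sup.n_fitted,
        "contact_cutoff": cfg.contact_cutoff,
        "neighbour_exclusion": cfg.neighbour_exclusion,
        "include_missing_as_other": cfg.include_missing_as_other,
    }

    return Report(
        header=header,
        resnum_a=_aligned([r.author_label for r in a.residues], alignment, "a"),
        resnum_b=_aligned([r.author_label for r in b.residues], alignment, "b"),
        seq_a=_aligned(list(a.sequence), alignment, "a"),
        seq_b=_aligned(list(b.sequence), alignment, "b"),
        ss_a={m: _aligned(asg_a[m].extended, alignment, "a") for m in usable},
        ss_b={m: _aligned(asg_b[m].extended, alignment, "b") for m in usable},
        consensus_a=_aligned(cons_a.states, alignment, "a"),
        consensus_b=_aligned(cons_b.states, alignment, "b"),
        bfactors_a=_aligned(pct_a, alignment, "a") if pct_a else [None] * len(alignment),
        bfactors_b=_aligned(pct_b, alignment, "b") if pct_b else [None] * len(alignment),
        differences=differences,
        ca_dist=de.ca_dist(a, b, alignment, sup),
        sc_dist=de.sc_dist_line(a, b, alignment),
        contacts=de.contacts_line(
            a, b, alignment, cfg.contact_cutoff, cfg.neighbour_exclusion
        ),
        summaries=summaries,
    )


# ---------------------------------------------------------------------------
# renderers

_CELL = 6  # printed characters per alignment position


def _fmt_cell(value, kind: str) -> str:
    if value is None:
        pad = "-" if kind in ("char", "resnum") else "."
        return f"{pad:>{_CELL}}"
    if kind == "char":
        return f"{value:>{_CELL}}"
    if kind == "resnum":
        return f"{value:>{_CELL}}"
    if kind == "dist":
        return f"{value:>{_CELL}.1f}"
    if kind == "int":
        return f"{int(round(value)):>{_CELL}d}"
    if kind == "flag":
        return f"{'*' if value else ' ':>{_CELL}}"
    raise ValueError(kind)


def render_text(report: Report, line_width: int = 100) -> str:
    """Column-aligned text blocks of every track, wrapped to ``line_width``.

    Distances print to 0.1 Å, percentiles and contact counts as integers,
    gaps as '-', undefined values as '.', differences as '*'.
    """
    label_w = 16
    per_block = max(1, (line_width - label_w) // _CELL)
    n = report.n_positions()

    rows: list[tuple[str, list, str]] = [("RESNUM A", report.resnum_a, "resnum"),
                                         ("SEQ A", report.seq_a, "char"),
                                         ("BFACTORS A", report.bfactors_a, "int")]
    for m in report.ss_a:
        rows.append((f"{METHOD_LABELS.get(m, m.upper())} A", report.ss_a[m], "char"))
    rows.append(("CONSENSUS A", report.consensus_a, "char"))
    for m in report.differences:
        label = "DIFFERENCES" if m == "consensus" else f"DIFF {METHOD_LABELS.get(m, m)}"
        rows.append((label, report.differences[m], "flag"))
    rows.append(("CA DIST", report.ca_dist, "dist"))
    rows.append(("SC DIST", report.sc_dist, "dist"))
    rows.append(("CONTACTS", report.contacts, "int"))
    rows.append(("CONSENSUS B", report.consensus_b, "char"))
    for m in report.ss_b:
        rows.append((f"{METHOD_LABELS.get(m, m.upper())} B", report.ss_b[m], "char"))
    rows.append(("BFACTORS B", report.bfactors_b, "int"))
    rows.append(("SEQ B", report.seq_b, "char"))
    rows.append(("RESNUM B", report.resnum_b, "resnum"))

    h = report.header
    lines = [
        f"chain A: {h['chain_a']['source']} model {h['chain_a']['model']} "
        f"chain {h['chain_a']['chain']} ({h['chain_a']['n_residues']} residues, "
        f"eff. resolution {h['chain_a']['effective_resolution']:.2f} A)",
        f"chain B: {h['chain_b']['source']} model {h['chain_b']['model']} "
        f"chain {h['chain_b']['chain']} ({h['chain_b']['n_residues']} residues, "
        f"eff. resolution {h['chain_b']['effective_resolution']:.2f} A)",
        f"methods: {', '.join(h['methods'])}   sequence identity: {h['identity']:.3f}",
        f"RMSD (fitted core, n={h['n_fitted']}): {h['rmsd']:.3f} A   "
        f"RMSD (all pairs): {h['rmsd_all_pairs']:.3f} A",
        "",
    ]
    for start in range(0, n, per_block):
        stop = min(start + per_block, n)
        for label, values, kind in rows:
            payload = "".join(_fmt_cell(v, kind) for v in values[start:stop])
            lines.append(f"{label:<{label_w}}{payload}")
        lines.append("")
    for name, s in report.summaries.items():
        title = {
            "whole_chain_a": "Summary of Whole Chain (A)",
            "whole_chain_b": "Summary of Whole Chain (B)",
            "selection_a": "Summary of Selection (A)",
            "selection_b": "Summary of Selection (B)",
        }.get(name, name)
        lines.append(
            f"{title}: H {s['pct_H']:.2f}%  E {s['pct_E']:.2f}%  O {s['pct_O']:.2f}%"
            f"  (X {s['pct_X']:.2f}%)  RMSD {s['rmsd']:.3f} A"
            f"  [{s['n_residues']} residues"
            + (f" + {s['n_missing']} missing" if s["n_missing"] else "")
            + "]"
        )
    return "\n".join(lines) + "\n"


def render_json(report: Report) -> str:
    """Schema-stable JSON with all tracks at full precision."""
    doc = {
        "header": report.header,
        "tracks": {
            "resnum_a": report.resnum_a,
            "resnum_b": report.resnum_b,
            "seq_a": report.seq_a,
            "seq_b": report.seq_b,
            "ss_a": report.ss_a,
            "ss_b": report.ss_b,
            "consensus_a": report.consensus_a,
            "consensus_b": report.consensus_b,
            "bfactors_a": report.bfactors_a,
            "bfactors_b": report.bfactors_b,
            "differences": report.differences,
            "ca_dist": report.ca_dist,
            "sc_dist": report.sc_dist,
            "contacts": report.contacts,
        },
        "summaries": report.summaries,
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def report_from_json(text: str) -> Report:
    """Rebuild a :class:`Report` from :func:`render_json` output."""
    doc = json.loads(text)
    t = doc["tracks"]
    return Report(
        header=doc["header"],
        resnum_a=t["resnum_a"], resnum_b=t["resnum_b"],
        seq_a=t["seq_a"], seq_b=t["seq_b"],
        ss_a=t["ss_a"], ss_b=t["ss_b"],
        consensus_a=t["consensus_a"], consensus_b=t["consensus_b"],
        bfactors_a=t["bfactors_a"], bfactors_b=t["bfactors_b"],
        differences=t["differences"],
        ca_dist=t["ca_dist"], sc_dist=t["sc_dist"], contacts=t["contacts"],
        summaries=doc["summaries"],
    )
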