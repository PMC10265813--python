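"""Deterministic JSON/markdown run reports."""

from __future__ import annotations

import json

from . import __version__
from .io_formats import _atomic_open, format_efficiency


def render_report(results: dict, config: dict | None = None,
                  seed: int | None = None, fmt: str = "json") -> str:
    """Render stage results with embedded config, seed and version.

    Ordering is deterministic (sorted keys) so identical inputs produce
    byte-identical reports.
    """
    payload = {
        "plastedit_version": __version__,
        "seed": seed,
        "config": config or {},
        "results": results,
    }
    if fmt == "json":
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if fmt == "markdown":
        lines = [
            "# plastedit report",
            "",
            f"- version: {__version__}",
            f"- seed: {seed}",
            "",
        ]
        for key in sorted(results):
            lines.append(f"## {key}")
            lines.append("")
            val = results[key]
            if isinstance(val, dict):
                for k in sorted(val, key=str):
                    lines.append(f"- {k}: {val[k]}")
            elif isinstance(val, list):
                lines.extend(f"- {v}" for v in val)
            else:
                lines.append(f"- {val}")
            lines.append("")
        return "\n".join(lines)
    raise ValueError(f"unknown report format {fmt!r}")


def sites_markdown_table(rows) -> str:
    """Printed-table-ordered markdown of editing sites (efficiency as
    two-decimal percentages)."""
    header = (
        "| Gene | Genome pos | Gene pos | Codon pos | Type | Codon change "
        "| AA change | Depth | Efficiency |"
    )
    sep = "|" + "---|" * 9
    lines = [header, sep]
    for r in rows:
        lines.append(
            f"| {r.gene} | {r.genome_pos} | {r.gene_pos} | {r.codon_pos} "
            f"| C->U | {r.ref_codon.replace('T', 'U')}->"
            f"{r.edited_codon.replace('T', 'U')} | {r.aa_ref}->{r.aa_alt} "
            f"| {r.depth} | {format_efficiency(r.efficiency)} |"
        )
    return "\n".join(lines) + "\n"


def write_report(text: str, path: str) -> None:
    with _atomic_open(path) as fh:
        fh.write(text)
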