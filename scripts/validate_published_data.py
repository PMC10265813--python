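#!/usr/bin/env python
"""Optional offline validation against the published accessions.

Several published figures cannot be recomputed from this repository alone
because they depend on external sequence records: the 24-genome variable /
parsimony-informative site counts and sliding-window diversity profile
(alignment of the deposited Rosa plastomes), and the chloroplast-to-
mitochondrion transfer inventory (R. chinensis accessions CM009589 /
CM009590). This script validates those analyses when the user supplies the
corresponding files locally; it NEVER attempts a download.

Usage:
    python scripts/validate_published_data.py \
        --alignment rosa_24_plastomes.aln.fasta \
        --cp CM009590.fasta --mt CM009589.fasta
"""

from __future__ import annotations

import argparse
import json
import sys


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alignment", help="MAFFT multi-FASTA alignment of the "
                                        "deposited plastome accessions")
    ap.add_argument("--cp", help="chloroplast genome FASTA (e.g. CM009590)")
    ap.add_argument("--mt", help="mitochondrial genome FASTA (e.g. CM009589)")
    args = ap.parse_args()

    if not (args.alignment or (args.cp and args.mt)):
        print(
            "This validation needs locally supplied accession files; none "
            "were given.\nProvide --alignment (24-plastome alignment) and/or "
            "--cp/--mt (CM009590/CM009589 FASTA).\nNo download is attempted "
            "by this script; fetch the accession records yourself, e.g. "
            "with NCBI datasets/efetch, then re-run.",
            file=sys.stderr,
        )
        return 2

    out = {}
    if args.alignment:
        from plastedit.diversity import (
            call_hotspots, read_alignment, site_classes, sliding_pi,
        )

        aln = read_alignment(args.alignment)
        windows = sliding_pi(aln, window=600, step=200)
        pis = [w.pi for w in windows if w.pi is not None]
        out["diversity"] = {
            **site_classes(aln),
            "pi_min": min(pis),
            "pi_max": max(pis),
            "hotspots_pi_gt_0.013": call_hotspots(windows, 0.013),
        }
    if args.cp and args.mt:
        from plastedit.io_formats import read_fasta
        from plastedit.structure import find_transfers, transfer_summary

        cp = read_fasta(args.cp)[0]
        mt = read_fasta(args.mt)[0]
        frags = find_transfers(cp, mt, min_identity=0.90, min_length=100)
        out["transfers"] = transfer_summary(frags, len(cp.seq))
    print(json.dumps(out, indent=2, sort_keys=True))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
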