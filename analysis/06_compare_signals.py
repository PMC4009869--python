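#!/usr/bin/env python
"""Quantify congruence between the gap and nucleotide signals:
Robinson-Foulds distances among all estimated trees, bootstrap-support
comparison classes, the gap tree rescaled to changes per nucleotide site,
and the branch-length correlation between data types.  Writes tables
under results/comparison/.
"""

import json
import warnings
from pathlib import Path

from gaptree import io_formats, treecompare, trees

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "comparison"


def main():
    warnings.simplefilter("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    paths = {
        "mp_all": ROOT / "parsimony" / "mp_all.nwk",
        "mp_gt1bp": ROOT / "parsimony" / "mp_gt1bp.nwk",
        "mp_gt2bp": ROOT / "parsimony" / "mp_gt2bp.nwk",
        "ml_gaps": ROOT / "likelihood" / "ml_gaps.nwk",
        "nuc": ROOT / "likelihood" / "ml_nucleotides.nwk",
        "combined": ROOT / "combined" / "combined.nwk",
        "true": ROOT / "simulated" / "true_tree.nwk",
    }
    loaded = {k: io_formats.read_tree(p) for k, p in paths.items() if p.exists()}

    rf = {}
    names = sorted(loaded)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rf[f"{a}__{b}"] = treecompare.rf_distance(loaded[a], loaded[b])
    print("Robinson-Foulds distances:")
    for k, v in sorted(rf.items()):
        print(f"  {k}: {v}")

    summary = {"rf_distances": rf}

    if "ml_gaps" in loaded and "nuc" in loaded:
        aug = json.loads((ROOT / "likelihood" / "summary.json").read_text())
        gaps_counts = json.loads((ROOT / "gaps" / "counts.json").read_text())
        n_gap = gaps_counts["all"]["total"] + aug["m_star"]
        aln = io_formats.read_alignment(ROOT / "simulated" / "alignment.fasta", "fasta")
        converted = treecompare.gap_rate_convert(loaded["ml_gaps"], n_gap, aln.n_columns)
        io_formats.write_tree(converted, OUT / "gap_tree_per_nucleotide_site.nwk")
        rel = converted.total_length() / loaded["nuc"].total_length()
        summary["gap_rate_relative_to_nucleotide"] = rel
        print(f"gap change rate = {rel:.3f} of the nucleotide substitution rate")

        comp = treecompare.branch_length_compare(loaded["nuc"], loaded["ml_gaps"])
        comp.pairs.to_csv(OUT / "branch_length_pairs.tsv", sep="\t", index=False)
        summary["branch_length_spearman"] = comp.correlation
        print(
            f"branch-length rank correlation (nuc vs gaps): {comp.correlation} "
            f"over {len(comp.pairs)} shared edges"
        )

    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
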