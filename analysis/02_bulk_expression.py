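"""Bulk stage: filters, TMM, differential expression, subfamily add-up.

Reads the simulated bulk counts, applies the 3-read and exon-overlap
filters, normalizes with genes-as-library-size TMM, tests treatment vs
control, aggregates TE loci per subfamily (all and intergenic modes)
and scores per-subfamily over-representation of upregulated loci.
"""

import json
from pathlib import Path

from tecre import genome_io, te_expression as tex

BASE = Path(__file__).resolve().parents[1] / "results"
SIM = BASE / "simulated"


def main() -> None:
    tes, genes, _ = genome_io.read_annotations(
        SIM / "tes.bed", SIM / "genes.gtf", SIM / "genome.sizes"
    )
    cm = tex.CountMatrix.read_tsv(SIM / "bulk_counts.tsv", SIM / "bulk_design.tsv")
    filtered = tex.filter_features(cm, tes, genes)
    print(f"{len(cm.counts)} features -> {len(filtered.counts)} after filters")

    factors = tex.tmm_normalize(filtered)
    print("TMM factors:", factors.tmm_factor.round(4).to_dict())

    de = tex.differential_expression(filtered, factors)
    de.table.to_csv(BASE / "bulk_de.tsv", sep="\t", index_label="feature")
    n_de = int(de.table["de"].sum())
    print(f"{n_de} features pass the FC>2 & p<0.05 rule")

    for mode in ("all", "intergenic"):
        agg = tex.aggregate_subfamily(filtered, tes, genes, mode=mode)
        agg.counts.to_csv(BASE / f"subfamily_counts_{mode}.tsv", sep="\t")

    enr = tex.subfamily_overrepresentation(de, tes, use_adjusted=False)
    enr.table.to_csv(BASE / "subfamily_overrepresentation.tsv", sep="\t")
    hits = enr.table[enr.table["adj_p"] < 0.05]
    truth = json.loads((SIM / "bulk_truth.json").read_text())
    planted_up = sorted(
        {k.rsplit("_", 1)[0] for k, v in truth["te_locus_lfc"].items() if v > 0}
    )
    print(f"over-represented subfamilies (BH<0.05): {sorted(hits.index)}")
    print(f"planted upregulated subfamilies:        {planted_up}")


if __name__ == "__main__":
    main()
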