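"""Repeat-family enrichment of the query peaks (shuffle z-score).

Reads the fixture rmsk catalog and planted-bias peak set, runs the
chromosome-stratified shuffle null (20 replicates, the pipeline default)
for each repeat family, and writes the ranked z-score table to
results/repeat_enrichment.tsv. Expected outcome: the Satellite family —
toward which peak placement was biased 10x — dominates the table, while
the dispersed LINE family sits near z = 0.
"""

from pathlib import Path

from chipms import ShuffleParams, enrich_catalog, read_chrom_sizes, read_intervals, read_rmsk_catalog, write_enrichment_table

SEED = 2026
ROOT = Path(__file__).resolve().parent.parent
FIX = ROOT / "results" / "fixtures"


def main() -> None:
    genome = read_chrom_sizes(FIX / "genome.chrom.sizes")
    peaks = read_intervals(FIX / "peaks.narrowPeak", dialect="narrowPeak", genome=genome)
    catalog = read_rmsk_catalog(FIX / "rmsk.tsv", group_by="repClass", genome=genome)
    table = enrich_catalog(peaks, catalog, genome, ShuffleParams(seed=SEED), genome_id="sim1Mb", peaks_id=peaks.name)
    out = ROOT / "results" / "repeat_enrichment.tsv"
    write_enrichment_table(table, out)
    print(f"wrote {out}")
    for r in table.rows:
        print(f"  {r.family_name:10s} observed={r.observed_bp:>7,} bp  "
              f"null={r.null_mean:>9.1f} +/- {r.null_sd:.1f}  z={r.z:+.2f}")
    top = table.rows[0]
    print(f"top family: {top.family_name} (z={top.z:.2f}) — the planted satellite bias is recovered"
          if top.family_name == "Satellite" else
          f"top family: {top.family_name} — unexpected, check the fixtures")


if __name__ == "__main__":
    main()
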