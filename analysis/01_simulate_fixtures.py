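"""Generate the synthetic study inputs with known ground truth.

Writes a fixture bundle under results/fixtures/: a 1 Mb genome with 5%
pericentromeric satellite and dispersed LINEs, a query peak set planted
with a 10x placement bias toward the satellite family, 20 unbiased
narrowPeak tracks (the screen's neutral families), and a 3-vs-3 log2
intensity matrix with 50 planted hits (log2FC = 3) under ~10% MNAR
missingness. Everything downstream reads these files through the same
parsers a real analysis would use.
"""

from pathlib import Path

from chipms import (
    GenomeSimSpec,
    PeakSimSpec,
    ProteomicsSimSpec,
    simulate_genome_and_repeats,
    simulate_intensity_matrix,
    simulate_peaks,
    total_bp,
)
from chipms.simulate import (
    write_chrom_sizes,
    write_group_map,
    write_intensity_tsv,
    write_narrowpeak,
    write_rmsk_table,
)

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, catalog = simulate_genome_and_repeats(GenomeSimSpec(seed=SEED))
    write_chrom_sizes(genome, OUT / "genome.chrom.sizes")
    write_rmsk_table(catalog, OUT / "rmsk.tsv")
    sat_bp = total_bp(catalog.families["Satellite"])
    line_bp = total_bp(catalog.families["LINE"])
    print(f"genome: {genome.total_bp:,} bp; Satellite {sat_bp:,} bp "
          f"({sat_bp / genome.total_bp:.1%}), LINE {line_bp:,} bp")

    peaks = simulate_peaks(
        genome, catalog, PeakSimSpec(bias_family="Satellite", bias_factor=10.0, seed=SEED + 1)
    )
    write_narrowpeak(peaks, OUT / "peaks.narrowPeak")
    print(f"query peaks: {len(peaks)} x 200 bp, placement bias rho=10 toward Satellite")

    tracks = OUT / "tracks"
    tracks.mkdir(exist_ok=True)
    for i in range(20):
        t = simulate_peaks(genome, catalog, PeakSimSpec(bias_factor=1.0, seed=SEED + 100 + i))
        write_narrowpeak(t, tracks / f"neutral_{i:02d}.narrowPeak")
    print(f"screen tracks: 20 unbiased narrowPeak files under {tracks}")

    m, is_hit = simulate_intensity_matrix(ProteomicsSimSpec(seed=SEED + 2))
    write_intensity_tsv(m, OUT / "intensities.tsv")
    write_group_map(m, OUT / "groups.tsv")
    with open(OUT / "truth_hits.txt", "w") as fh:
        for pid, h in zip(m.values.index, is_hit):
            if h:
                fh.write(f"{pid}\n")
    frac = m.values.isna().to_numpy().mean()
    print(f"intensity matrix: {m.values.shape[0]} proteins x {m.values.shape[1]} samples, "
          f"{int(is_hit.sum())} planted hits, {frac:.1%} missing (MNAR)")
    print(f"wrote fixtures to {OUT}")


if __name__ == "__main__":
    main()
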