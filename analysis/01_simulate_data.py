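"""Generate the synthetic study inputs with planted ground truth.

Writes, under results/data/: a ten-population elution trace, a three-replicate
protein-group table over fractions 23-50 with ten planted complexes, the
matching reference complex set, a reference proteome list, and a ten-module
GO-BP annotation table with 5% flip noise.
"""
from pathlib import Path

from cofrac.peaks import GaussianComponent
from cofrac.simulate import (generate_annotation, generate_cofractionation,
                             generate_trace)

SEED = 17
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    amps = [0.35, 0.55, 1.0, 0.75, 0.6, 0.5, 0.4, 0.3, 0.25, 0.2]
    comps = [GaussianComponent(a, 25.0 + 3.4 * i, 1.15)
             for i, a in enumerate(amps)]
    trace, trace_truth = generate_trace(comps, snr=80.0,
                                        grid=(20.0, 63.0, 0.1), seed=SEED)
    trace.to_csv(OUT / "trace.csv")

    table, truth = generate_cofractionation(seed=SEED)
    table.to_tsv(OUT / "protein_groups.tsv")
    truth.reference_complexes().to_tsv(OUT / "reference_complexes.tsv")

    assay_proteins = sorted(table.meta.index[~table.meta.is_decoy
                                             & ~table.meta.is_contaminant])
    # 480 background-only proteins widen the annotation universe so that
    # over-representation of the assayed proteome is testable
    background = [f"B{20000 + i}" for i in range(480)]
    annotation, ann_truth = generate_annotation(assay_proteins, n_modules=10,
                                                terms_per_module=8,
                                                flip_noise=0.05,
                                                background_proteins=background,
                                                background_rate=0.01,
                                                seed=SEED)
    annotation.to_tsv(OUT / "annotation.tsv")

    # reference proteome list: half the assay proteins, emulating partial
    # overlap with a previously reported lipoprotein proteome
    (OUT / "reference_proteome.txt").write_text(
        "\n".join(assay_proteins[: len(assay_proteins) // 2]) + "\n")

    truth.trace_components = trace_truth.trace_components
    truth.baseline = trace_truth.baseline
    truth.noise_sd = trace_truth.noise_sd
    truth.modules = ann_truth.modules
    truth.module_terms = ann_truth.module_terms
    truth.to_json(OUT / "ground_truth.json")

    print(f"planted {len(comps)} trace populations, "
          f"{len(truth.complexes)} complexes over {len(assay_proteins)} "
          f"proteins, {len(truth.modules)} annotation modules -> {OUT}")


if __name__ == "__main__":
    main()
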