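"""Shared end-to-end pipeline used by regression tests and golden files."""

from pathlib import Path

from miragg import aggregate, build_rank_matrix, evaluate, rank_pathways
from miragg.evaluation import LabeledRanking
from miragg.io import load_sources, read_gmt, read_labels, write_metrics, write_predictions
from miragg.simulate import make_fixture

GOLDEN_DIR = Path(__file__).parent / "golden"
GOLDEN_FILES = ("aggregated.tsv", "metrics.json", "pathway_report.tsv")


def build_tiny_outputs(out_dir: Path) -> dict[str, Path]:
    """Run the whole worked example on the tiny fixture, writing all outputs.

    simulate(tiny, seed 7) -> aggregate(mean) -> evaluate -> pathway report
    for the miRNA of the top-ranked interaction, at the recommended 0.05
    score threshold.  Every file is written with the package's own writers, so the
    bytes are reproducible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixture = make_fixture("tiny", out_dir / "fixture", seed=7)

    sources = load_sources(fixture["config"])
    matrix = build_rank_matrix(sources)
    result = aggregate(matrix, method="mean")
    agg_path = write_predictions(result, out_dir / "aggregated.tsv")

    labels = read_labels(fixture["labels"])
    data = LabeledRanking.from_frames(result, labels)
    summary = evaluate(data.scores, data.labels)
    metrics_path = write_metrics(summary.to_dict(), out_dir / "metrics.json")

    top_mirna = result.iloc[0]["mirna"]
    targets = result[result["mirna"] == top_mirna]
    report = rank_pathways(
        targets, read_gmt(fixture["pathways"]), validated=labels, threshold=0.05
    )
    report_path = out_dir / "pathway_report.tsv"
    report.to_csv(report_path, sep="\t", index=False, float_format="%.10g")

    return {
        "aggregated.tsv": agg_path,
        "metrics.json": metrics_path,
        "pathway_report.tsv": report_path,
    }
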