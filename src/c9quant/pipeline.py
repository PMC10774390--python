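"""End-to-end pipeline driver: reads -> calls -> alleles -> edits, plus
ddPCR and MSD stages when their inputs are present.

Each stage that can run does; a stage failure is recorded in the report
and partial outputs are kept (exit status reflects hard errors only).
Reports are deterministic for identical config and inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

from . import alleles as alleles_mod
from . import ddpcr as ddpcr_mod
from . import edits as edits_mod
from . import io as io_mod
from . import msd as msd_mod
from . import repeatcall
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def _template_from_fasta(path: str) -> str:
    from Bio import SeqIO

    recs = list(SeqIO.parse(path, "fasta"))
    if not recs:
        raise ValueError(f"no template sequence in {path}")
    return str(recs[0].seq)


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> dict:
    """Run every stage whose inputs are configured; return the report.

    Writes a JSON report plus per-stage CSV/JSON tables under the output
    directory.  Raises only when no stage has any input or the read input
    is empty/unreadable before any stage has produced output.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "errors": {}}
    th = config.thresholds

    if not (config.reads or config.droplets_csv or config.msd_csv):
        raise ValueError("pipeline config provides no inputs")

    calls = None
    if config.reads:
        reads = io_mod.read_reads(config.reads)
        if not reads:
            raise ValueError(f"no reads parsed from {config.reads}")
        calls = repeatcall.call_reads(reads, config.locus)
        table = repeatcall.calls_to_frame(calls)
        table.to_csv(out / "repeat_calls.csv", index=False)
        (out / "waterfall.json").write_text(
            json.dumps(repeatcall.waterfall_tracks(calls), indent=1)
        )
        report["stages"]["repeatcall"] = {
            "n_reads": len(reads),
            "n_on_target": int(table["on_target"].sum()),
        }

        try:
            c1, c2 = alleles_mod.cluster_alleles(
                calls,
                config.locus,
                min_reads_per_allele=th.min_reads_per_allele,
            )
            summaries = [alleles_mod.summarize_allele(c1)]
            if c2 is not None:
                summaries.append(alleles_mod.summarize_allele(c2))
            (out / "alleles.json").write_text(json.dumps(summaries, indent=1))
            report["stages"]["alleles"] = summaries
        except ValueError as exc:
            report["errors"]["alleles"] = str(exc)

        if config.templates:
            try:
                templates = {
                    label: _template_from_fasta(path)
                    for label, path in config.templates.items()
                }
                clone = edits_mod.analyze_clone(
                    reads,
                    templates,
                    config.locus,
                    min_outcome_fraction=th.min_outcome_fraction,
                    retained_min_repeats=th.retained_min_repeats,
                )
                clone_dict = edits_mod.report_to_dict(clone)
                (out / "clonality.json").write_text(json.dumps(clone_dict, indent=1))
                report["stages"]["edits"] = clone_dict
            except (ValueError, OSError) as exc:
                report["errors"]["edits"] = str(exc)

    if config.droplets_csv:
        try:
            wells = io_mod.read_droplet_csv(config.droplets_csv)
            quants = ddpcr_mod.quantify(
                wells, min_positive_droplets=th.ddpcr_min_positive_droplets
            )
            qframe = ddpcr_mod.quants_to_frame(quants.values())
            qframe.to_csv(out / "ddpcr_quant.csv", index=False)
            fractions = {}
            for sample in {s for s, _ in quants}:
                v2, v3 = quants.get((sample, "V2")), quants.get((sample, "V3"))
                if v2 and v3:
                    f2, f3 = ddpcr_mod.variant_fractions(v2, v3)
                    fractions[sample] = {"fraction_V2": f2, "fraction_V3": f3}
            report["stages"]["ddpcr"] = {
                "n_quantified": len(quants),
                "variant_fractions": fractions,
            }
        except (ValueError, OSError) as exc:
            report["errors"]["ddpcr"] = str(exc)

    if config.msd_csv:
        try:
            wells = io_mod.read_msd_csv(config.msd_csv)
            table = msd_mod.summarize_screen(
                wells, threshold=th.msd_ratio_threshold
            )
            table.to_csv(out / "msd_ratios.csv", index=False)
            flagged = (
                sorted(
                    set(
                        zip(
                            table[table["flagged"]]["capture_ab"],
                            table[table["flagged"]]["detection_ab"],
                        )
                    )
                )
                if not table.empty
                else []
            )
            report["stages"]["msd"] = {
                "n_ratios": len(table),
                "flagged_pairs": [list(p) for p in flagged],
            }
        except (ValueError, OSError) as exc:
            report["errors"]["msd"] = str(exc)

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
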