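"""File I/O: FASTA/FASTQ via Biopython, tabular artifacts via pandas.

All writers produce deterministic byte output for a given input (stable
column orders, floats to 6 decimals, sorted JSON keys).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import ReadPair
from .types import ProtospacerHit, to_plain

ANNOTATION_COLUMNS = ["scaffold", "start", "end", "strand", "product"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq_pair(pairs: Sequence[ReadPair], path_r1, path_r2) -> None:
    """Mate FASTQ files; qualities are constant 'I' (no stage consumes them)."""
    def records(idx):
        for p in pairs:
            seq = p.r1 if idx == 1 else p.r2
            rec = SeqRecord(Seq(seq), id=f"{p.name}/{idx}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    SeqIO.write(records(1), str(path_r1), "fastq")
    SeqIO.write(records(2), str(path_r2), "fastq")


def read_fastq_pairs(path_r1, path_r2) -> list[ReadPair]:
    r1 = list(SeqIO.parse(str(path_r1), "fastq"))
    r2 = list(SeqIO.parse(str(path_r2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("mate files differ in read count")
    pairs = []
    for a, b in zip(r1, r2):
        name = a.id.rsplit("/", 1)[0]
        pairs.append(ReadPair(name, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bins(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", names=["scaffold", "bin"], header=None,
                     comment="#")
    if list(df.iloc[0]) == ["scaffold", "bin"]:
        df = df.iloc[1:]
    return dict(zip(df["scaffold"], df["bin"]))


def write_bins(bins: dict[str, str], path) -> None:
    pd.DataFrame(
        {"scaffold": list(bins), "bin": list(bins.values())}
    ).to_csv(path, sep="\t", index=False)


def hits_frame(hits: Iterable[ProtospacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"spacer_id": h.spacer_id, "scaffold": h.target_scaffold,
             "start": h.start, "end": h.end, "strand": h.strand,
             "mismatches": h.mismatches, "coverage": h.coverage}
            for h in hits
        ],
        columns=["spacer_id", "scaffold", "start", "end", "strand",
                 "mismatches", "coverage"],
    )


def write_hits(hits, path_tsv, path_bed=None) -> None:
    df = hits_frame(hits)
    df.to_csv(path_tsv, sep="\t", index=False)
    if path_bed is not None:
        bed = df[["scaffold", "start", "end", "spacer_id", "mismatches", "strand"]]
        bed.to_csv(path_bed, sep="\t", index=False, header=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(to_plain(obj)), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def write_scenario(scenario, out_dir) -> dict[str, Path]:
    """Write a generated scenario as FASTA/FASTQ/TSV/JSON artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffolds": out / "scaffolds.fasta",
        "r1": out / "reads_R1.fastq",
        "r2": out / "reads_R2.fastq",
        "annotations": out / "annotations.tsv",
        "bins": out / "bins.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(scenario.scaffolds, paths["scaffolds"])
    write_fastq_pair(scenario.reads, paths["r1"], paths["r2"])
    write_annotations(scenario.annotations, paths["annotations"])
    write_bins(scenario.bins, paths["bins"])
    scenario.truth.to_json(paths["truth"])
    return paths
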