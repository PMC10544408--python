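"""Reading and writing the standard formats (FASTA/FASTQ/TSV/JSON)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import CountTable, EnrichmentEstimate, ReadDataset


def read_condition_files(paths, alphabet: str = "dna") -> ReadDataset:
    """Build a ReadDataset from one FASTA/FASTQ file per condition.

    ``paths[j]`` supplies the reads labeled with condition ``j`` (0 is
    conventionally pre-selection). Format is sniffed from the extension.
    """
    records = []
    for label, path in enumerate(paths):
        fmt = "fastq" if str(path).lower().endswith(("fq", "fastq")) else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            records.append((str(rec.seq).upper(), label))
    return ReadDataset(records, alphabet=alphabet, k=len(list(paths)) - 1)


def write_reads(path, reads, fmt: str = "fastq", prefix: str = "read"):
    """Write read strings to FASTA/FASTQ (constant placeholder qualities)."""
    recs = []
    for i, s in enumerate(reads):
        rec = SeqRecord(Seq(s), id=f"{prefix}{i}", description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(s)
        recs.append(rec)
    SeqIO.write(recs, str(path), fmt)


def read_count_table(path, alphabet: str = "dna") -> CountTable:
    """TSV with header ``sequence<TAB>count_0<TAB>count_1...``."""
    df = pd.read_csv(path, sep="\t")
    count_cols = [c for c in df.columns if c.startswith("count_")]
    if "sequence" not in df.columns or not count_cols:
        raise ValueError("count table needs 'sequence' and 'count_*' columns")
    return CountTable(df["sequence"].tolist(),
                      df[count_cols].to_numpy(dtype=np.int64),
                      alphabet=alphabet)


def write_count_table(path, table: CountTable):
    cols = {"sequence": table.sequences}
    for j in range(table.n_conditions):
        cols[f"count_{j}"] = table.counts[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_enrichment(path, table: CountTable, estimate: EnrichmentEstimate):
    """TSV of counts plus log_e / sigma2 / weight columns."""
    cols = {"sequence": table.sequences}
    for j in range(table.n_conditions):
        cols[f"count_{j}"] = table.counts[:, j]
    cols["log_e"] = estimate.log_e
    if estimate.sigma2 is not None:
        cols["sigma2"] = estimate.sigma2
        cols["weight"] = estimate.weight
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_predictions(path, sequences, predictions, column: str = "pred_log_e"):
    preds = np.atleast_2d(np.asarray(predictions))
    if preds.shape[0] != len(sequences):
        preds = preds.T
    cols = {"sequence": list(sequences)}
    if preds.shape[1] == 1:
        cols[column] = preds[:, 0]
    else:
        for j in range(preds.shape[1]):
            cols[f"{column}_{j}"] = preds[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
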