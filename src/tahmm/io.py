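"""FASTA input/output, model-bundle serialization and prediction tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AminoAcidSequence, SequenceError
from .hmm import TOPOLOGY_VERSION, HmmParameters
from .training import ModelBundle


class FastaError(ValueError):
    pass


class BundleError(ValueError):
    pass


def read_fasta(path) -> list[AminoAcidSequence]:
    """Read a multi-record FASTA file into validated sequences.

    Record order and ids are preserved; mixed-case input is canonicalised
    to uppercase.  Empty files, duplicate ids and residues outside the
    canonical alphabet plus ambiguity codes raise descriptive errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[AminoAcidSequence] = []
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(AminoAcidSequence(rec.id, str(rec.seq)))
        except SequenceError as exc:
            raise FastaError(f"{path}: {exc}") from exc
    return out


def write_fasta(seqs, path, width: int = 60) -> None:
    """Write sequences (or synthetic records) as wrapped FASTA."""
    records = []
    for s in seqs:
        s = getattr(s, "sequence", s)  # accept SyntheticRecord
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ----------------------------------------------------------------------
# Model bundles
# ----------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a bundle to JSON with linear probabilities.

    Floats are written with ``repr`` (shortest round-trip) so that loading
    reproduces every probability bit-exactly.
    """
    data = {
        "topology_version": TOPOLOGY_VERSION,
        "ta": {str(k): m.to_dict() for k, m in bundle.ta.items()},
        "sp": bundle.sp.to_dict(),
        "mp": bundle.mp.to_dict(),
        "metadata": bundle.metadata,
        "thresholds": bundle.thresholds,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_bundle(path) -> ModelBundle:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"{path}: not valid JSON ({exc})") from exc
    version = data.get("topology_version")
    if version != TOPOLOGY_VERSION:
        raise BundleError(
            f"{path}: topology version {version!r} does not match "
            f"{TOPOLOGY_VERSION!r}"
        )
    for key in ("ta", "sp", "mp"):
        if key not in data:
            raise BundleError(f"{path}: missing model key {key!r}")
    try:
        ta = {
            int(k): HmmParameters.from_dict(m) for k, m in data["ta"].items()
        }
        sp = HmmParameters.from_dict(data["sp"])
        mp = HmmParameters.from_dict(data["mp"])
    except ValueError as exc:
        raise BundleError(f"{path}: {exc}") from exc
    return ModelBundle(
        ta=ta,
        sp=sp,
        mp=mp,
        metadata=data.get("metadata", {}),
        thresholds=data.get("thresholds", {}),
    )


# ----------------------------------------------------------------------
# Prediction tables
# ----------------------------------------------------------------------

def predictions_to_frame(records) -> pd.DataFrame:
    """Tabulate prediction records; coordinates 1-based inclusive."""
    rows = []
    for r in records:
        tmds = [s for s in r.segments if s.region == "TMD"]
        tails = [s for s in r.segments if s.region == "tail"]
        tmd = max(tmds, key=len) if tmds else None
        rows.append(
            {
                "id": r.id,
                "length": r.length,
                "ln_l_ta": r.ln_l_ta,
                "ln_l_sp": r.ln_l_sp,
                "ln_l_mp": r.ln_l_mp,
                "S_sp": r.s_sp,
                "S_mp": r.s_mp,
                "tmd_start": tmd.start + 1 if tmd else "",
                "tmd_end": tmd.end if tmd else "",
                "tail_length": len(tails[-1]) if tails else 0,
                "decode_verdict": r.decoding_verdict,
                "decode_failure": r.decoding_failure or "",
                "score_verdict": r.score_verdict,
                "combined_verdict": r.combined_verdict,
            }
        )
    return pd.DataFrame(rows)


def write_predictions(records, path) -> None:
    predictions_to_frame(records).to_csv(path, sep="\t", index=False)
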