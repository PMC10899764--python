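"""File formats: FASTA/GenBank sequences, specificity profiles,
observation documents and structured reports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import CIRCULAR, LINEAR, DuplexSequence
from .methylation import MTaseSpecificity
from .inference import ObservedPattern

PathLike = Union[str, Path]


def read_sequence(path: PathLike, fmt: Optional[str] = None,
                  topology: Optional[str] = None) -> DuplexSequence:
    """Read the first record of a FASTA or GenBank file.

    GenBank topology comes from the LOCUS line; FASTA defaults to circular
    (plasmids are the common substrate here).  ``topology`` overrides both.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    record = next(SeqIO.parse(str(path), fmt))
    if topology is None:
        if fmt == "genbank":
            topology = record.annotations.get("topology", LINEAR)
        else:
            topology = CIRCULAR
    return DuplexSequence(str(record.seq), topology, name=record.id)


def write_sequence(seq: DuplexSequence, path: PathLike, fmt: Optional[str] = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    record = SeqRecord(Seq(seq.residues), id=seq.name or "sequence", description="")
    if fmt == "genbank":
        record.annotations["molecule_type"] = "DNA"
        record.annotations["topology"] = seq.topology
    SeqIO.write([record], str(path), fmt)


def read_fasta_many(path: PathLike, topology: str = LINEAR) -> list[DuplexSequence]:
    return [DuplexSequence(str(r.seq), topology, name=r.id)
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta_many(seqs: Iterable[DuplexSequence], path: PathLike) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.name or f"seq{i}", description="")
               for i, s in enumerate(seqs, 1)]
    SeqIO.write(records, str(path), "fasta")


def sequence_checksum(seq: DuplexSequence) -> str:
    return hashlib.sha256(seq.residues.encode()).hexdigest()[:16]


# -- specificity profiles --------------------------------------------------

def _spec_from_mapping(name: str, doc: dict) -> MTaseSpecificity:
    return MTaseSpecificity(
        name=name,
        core=frozenset(doc.get("core", [])),
        flank5_weights=doc.get("flank5_weights", {}),
        flank3_weights=doc.get("flank3_weights", {}),
        efficiency=doc.get("efficiency", 1.0),
    )


def load_profiles(path: Optional[PathLike] = None) -> dict[str, MTaseSpecificity]:
    """Load specificity profiles from YAML (the shipped file by default)."""
    if path is None:
        from importlib.resources import files
        text = files("mtasekit.data").joinpath("profiles.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    return {name: _spec_from_mapping(name, d) for name, d in doc.items()}


def save_profiles(profiles: dict[str, MTaseSpecificity], path: PathLike) -> None:
    doc = {}
    for name, spec in profiles.items():
        doc[name] = {
            "core": sorted(spec.core),
            "flank5_weights": spec.flank5_weights,
            "flank3_weights": spec.flank3_weights,
            "efficiency": spec.efficiency,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def parse_mtase_argument(text: str, profiles: Optional[dict] = None) -> MTaseSpecificity:
    """Resolve an ``--mtase`` value: a profile name, a core list like
    "CG" or "CC+CA", or an inline spec "CC:3A=1,3C=0.6,5A=0.4"."""
    if profiles is None:
        profiles = load_profiles()
    if text in profiles:
        return profiles[text]
    if ":" not in text:
        return MTaseSpecificity.simple(text.replace(",", "+").split("+"))
    core_part, weight_part = text.split(":", 1)
    f5, f3 = {}, {}
    for item in filter(None, weight_part.split(",")):
        key, val = item.split("=")
        side, base = key[0], key[1].upper()
        target = {"5": f5, "3": f3}.get(side)
        if target is None:
            raise ValueError(f"flank side must be 5 or 3 in {item!r}")
        target[base] = float(val)
    return MTaseSpecificity(text, frozenset(core_part.split("+")),
                            flank5_weights=f5, flank3_weights=f3)


# -- observations ----------------------------------------------------------

def load_observations(path: PathLike) -> list[ObservedPattern]:
    """Observations as YAML/JSON: a list of {enzyme, bands, flags} docs."""
    doc = yaml.safe_load(Path(path).read_text())
    out = []
    for item in doc:
        out.append(ObservedPattern(
            enzyme=item["enzyme"],
            bands=tuple(item.get("bands", ())),
            full_length_linear=bool(item.get("full_length_linear", False)),
            uncut=bool(item.get("uncut", False)),
        ))
    return out


def write_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
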