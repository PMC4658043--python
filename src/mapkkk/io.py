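"""Plain-text io helpers: GMT-like gene sets and one-id-per-line lists."""

from __future__ import annotations

from typing import Mapping, Sequence


def read_gmt(path) -> dict[str, list[str]]:
    """GMT-like TSV: term, description, then tab-separated gene ids."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


def write_gmt(path, genesets: Mapping[str, Sequence[str]], descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, genes in genesets.items():
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_id_list(path, ids: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
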