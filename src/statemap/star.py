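"""Minimal STAR file reader/writer for RELION particles tables.

Supports the RELION 3.1 dialect: a file of one or more ``data_`` blocks,
each either a loop (``loop_`` + ``_rln...`` column tags + whitespace rows)
or simple key-value pairs.  Only what the orientation filter needs is
implemented — no multi-line values, no quoted strings with embedded
whitespace beyond simple double quotes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_star", "write_star", "StarParseError"]


class StarParseError(ValueError):
    """Raised on malformed STAR input, naming the offending line."""


def read_star(path: str | Path) -> dict[str, pd.DataFrame]:
    """Parse a STAR file into ``{block_name: DataFrame}``.

    Loop blocks become row-per-particle frames with the ``_rln`` prefix
    stripped from column names; key-value blocks become single-row frames.
    Numeric columns are converted where possible.
    """
    path = Path(path)
    blocks: dict[str, pd.DataFrame] = {}
    name: str | None = None
    in_loop = False
    columns: list[str] = []
    rows: list[list[str]] = []
    kv: dict[str, str] = {}

    def flush() -> None:
        nonlocal columns, rows, kv
        if name is None:
            return
        if columns:
            df = pd.DataFrame(rows, columns=columns)
        elif kv:
            df = pd.DataFrame([kv])
        else:
            columns, rows, kv = [], [], {}
            return
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            if not converted.isna().any():
                df[col] = converted
        blocks[name] = df
        columns, rows, kv = [], [], {}

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                flush()
                name = line[len("data_"):] or "default"
                in_loop = False
                continue
            if line == "loop_":
                in_loop = True
                continue
            if line.startswith("_"):
                tag = line.split()[0].lstrip("_")
                if tag.startswith("rln"):
                    tag = tag[len("rln"):]
                    tag = tag[:1].lower() + tag[1:]  # RELION CamelCase -> camelCase
                if in_loop:
                    columns.append(tag)
                else:
                    parts = line.split(None, 1)
                    if len(parts) != 2:
                        raise StarParseError(f"{path}:{lineno}: tag without value")
                    kv[tag] = parts[1].strip('"')
                continue
            if name is None:
                raise StarParseError(f"{path}:{lineno}: data outside any data_ block")
            if not in_loop or not columns:
                raise StarParseError(f"{path}:{lineno}: row outside a loop")
            values = line.split()
            if len(values) != len(columns):
                raise StarParseError(
                    f"{path}:{lineno}: {len(values)} values for {len(columns)} columns")
            rows.append(values)
    flush()
    if not blocks:
        raise StarParseError(f"{path}: no data blocks found")
    return blocks


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def write_star(blocks: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write ``{block_name: DataFrame}`` as a RELION-style STAR file.

    Every block is emitted as a loop with ``_rln``-prefixed numbered tags.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# version 30001\n")
        for name, df in blocks.items():
            fh.write(f"\ndata_{name}\n\nloop_\n")
            for i, col in enumerate(df.columns, start=1):
                fh.write(f"_rln{col[:1].upper()}{col[1:]} #{i}\n")
            for row in df.itertuples(index=False):
                fh.write("  ".join(_fmt(v) for v in row) + "\n")
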