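"""Exact serialization of joint distributions to CSV and JSON.

Weights are written as integer or ``"num/den"`` strings, never floats,
so a write followed by a read reproduces the distribution exactly for
any rational success probability.  The CSV uses the conventional table
layout — rows ``c = 0..n-1``, columns ``l = 1..n`` — with leading
``#``-comment lines carrying the metadata.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import TextIO, Union

from .pmf import JointPMF, Rational, _normalize_rational

__all__ = [
    "format_rational",
    "parse_rational",
    "pmf_to_csv",
    "pmf_from_csv",
    "pmf_to_json",
    "pmf_from_json",
]

PathLike = Union[str, Path]


def format_rational(x: Rational) -> str:
    """``741`` -> ``"741"``, ``Fraction(2716, 32768)`` -> ``"679/8192"``."""
    x = _normalize_rational(x)
    return str(x)


def parse_rational(s: str) -> Rational:
    """Inverse of :func:`format_rational`; accepts ints, a/b and decimals."""
    return _normalize_rational(Fraction(s.strip()))


def _open_for(target: Union[PathLike, TextIO], mode: str):
    if hasattr(target, "read") or hasattr(target, "write"):
        return target, False
    return open(target, mode), True


def pmf_to_csv(pmf: JointPMF, target: Union[PathLike, TextIO]) -> None:
    """Write the matrix in table layout with exact entries."""
    fh, close = _open_for(target, "w")
    try:
        fh.write(f"# n={pmf.n}\n")
        fh.write(f"# scale={pmf.scale}\n")
        fh.write(f"# m={pmf.m}\n")
        fh.write(f"# conditioning={pmf.conditioning}\n")
        fh.write("," + ",".join(f"l={l}" for l in range(1, pmf.n + 1)) + "\n")
        for c in range(pmf.n):
            row = ",".join(format_rational(v) for v in pmf.weights[c])
            fh.write(f"c={c},{row}\n")
    finally:
        if close:
            fh.close()


def pmf_from_csv(source: Union[PathLike, TextIO]) -> JointPMF:
    """Read a matrix written by :func:`pmf_to_csv`."""
    fh, close = _open_for(source, "r")
    try:
        meta = {}
        rows = []
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            elif not header_seen:
                header_seen = True  # the "l=1,...,l=n" header row
            else:
                cells = line.split(",")
                rows.append([parse_rational(v) for v in cells[1:]])
    finally:
        if close:
            fh.close()
    n = int(meta.get("n", len(rows)))
    return JointPMF(
        n,
        rows,
        scale=meta.get("scale", "probability"),
        m=int(meta.get("m", 2)),
        conditioning=meta.get("conditioning", "unconditional"),
    )


def pmf_to_json(pmf: JointPMF, target: Union[PathLike, TextIO, None] = None) -> str:
    """Serialize to a JSON document; returns the string, optionally writing it."""
    doc = {
        "n": pmf.n,
        "scale": pmf.scale,
        "m": pmf.m,
        "conditioning": pmf.conditioning,
        "weights": [
            [format_rational(v) for v in pmf.weights[c]] for c in range(pmf.n)
        ],
    }
    text = json.dumps(doc, indent=1)
    if target is not None:
        fh, close = _open_for(target, "w")
        try:
            fh.write(text)
        finally:
            if close:
                fh.close()
    return text


def pmf_from_json(source: Union[PathLike, TextIO, str]) -> JointPMF:
    """Read a distribution written by :func:`pmf_to_json`."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        fh, close = _open_for(source, "r")
        try:
            doc = json.load(fh)
        finally:
            if close:
                fh.close()
    weights = [[parse_rational(v) for v in row] for row in doc["weights"]]
    return JointPMF(
        doc["n"],
        weights,
        scale=doc["scale"],
        m=doc["m"],
        conditioning=doc["conditioning"],
    )
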