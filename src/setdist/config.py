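"""Plain-text key=value run configuration.

Recognized keys (all optional, shown with defaults)::

    alphabet=DNA            # DNA | RNA | PROTEIN
    words=1-grams           # k-grams | explicit comma list, e.g. words=AA,AC
    transform=identity      # identity | power:<q> (power:2 is the quadratic map)
    centered=true           # covariance estimator: centered | uncentered moment
    frequencies=false       # length-normalized features instead of raw counts
    rule=mean               # classification rule: mean | min | median
    linkage=average         # clustering linkage: average | complete | single
    k=2                     # number of clusters
    seed=                   # integer seed for stochastic subcommands

Lines starting with ``#`` and blank lines are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .features import ALPHABETS, Alphabet, TransformSpec, WordSet

__all__ = ["RunConfig", "parse_config"]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


@dataclass
class RunConfig:
    alphabet: str = "DNA"
    words: str = "1-grams"
    transform: str = "identity"
    centered: bool = True
    frequencies: bool = False
    rule: str = "mean"
    linkage: str = "average"
    k: int = 2
    seed: int | None = None

    def resolve_alphabet(self) -> Alphabet:
        try:
            return ALPHABETS[self.alphabet.upper()]
        except KeyError:
            raise ValueError(f"unknown alphabet {self.alphabet!r}; expected one of {sorted(ALPHABETS)}")

    def resolve_words(self) -> WordSet:
        alphabet = self.resolve_alphabet()
        m = re.fullmatch(r"(\d+)-grams?", self.words.strip())
        if m:
            return WordSet.ngrams(alphabet, int(m.group(1)))
        words = tuple(w.strip().upper() for w in self.words.split(",") if w.strip())
        return WordSet(words, alphabet)

    def resolve_transform(self) -> TransformSpec:
        t = self.transform.strip().lower()
        if t == "identity":
            return TransformSpec.identity()
        m = re.fullmatch(r"power:([0-9.]+)", t)
        if m:
            return TransformSpec.elementwise_power(float(m.group(1)))
        raise ValueError(f"unknown transform {self.transform!r}; expected 'identity' or 'power:<q>'")


def parse_config(path) -> RunConfig:
    """Parse a key=value config file into a validated RunConfig."""
    cfg = RunConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in {"alphabet", "words", "transform", "rule", "linkage"}:
            setattr(cfg, key, value)
        elif key in {"centered", "frequencies"}:
            if value.lower() not in _BOOL:
                raise ValueError(f"{path}:{lineno}: invalid boolean {value!r}")
            setattr(cfg, key, _BOOL[value.lower()])
        elif key == "k":
            cfg.k = int(value)
        elif key == "seed":
            cfg.seed = int(value) if value else None
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    # fail fast on anything inconsistent
    cfg.resolve_words()
    cfg.resolve_transform()
    if cfg.rule not in {"mean", "min", "median"}:
        raise ValueError(f"unknown rule {cfg.rule!r}")
    if cfg.linkage not in {"average", "complete", "single"}:
        raise ValueError(f"unknown linkage {cfg.linkage!r}")
    if cfg.k < 1:
        raise ValueError("k must be >= 1")
    return cfg
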