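"""Pluggable RNA folding engines emitting dot-bracket structures.

The default engine is a maximum-base-pairing (Nussinov-style) folder with a
minimum hairpin loop of 3 and Watson-Crick + GU wobble pairs.  Concealment
judgement (:func:`agscan.zones.ag_concealment`) is decoupled from folding, so
any callable ``seq -> dot_bracket`` — e.g. a wrapper around an external
minimum-free-energy program such as RNAfold — can be substituted.
"""

from __future__ import annotations

import shutil
import subprocess
from functools import lru_cache

PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


@lru_cache(maxsize=4096)
def nussinov_fold(seq: str, min_loop: int = MIN_LOOP) -> str:
    """Maximum base-pairing dot-bracket structure of an RNA/DNA string.

    DNA input is accepted (T read as U).  Ties are broken toward unpaired
    ends, which keeps the traceback deterministic.
    """
    rna = seq.upper().replace("T", "U")
    n = len(rna)
    if n == 0:
        return ""
    best = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            cand = best[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if _can_pair(rna[k], rna[j]):
                    left = best[i][k - 1] if k > i else 0
                    cand = max(cand, left + 1 + best[k + 1][j - 1])
            best[i][j] = cand

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j - i > min_loop:
            if best[i][j] == best[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - min_loop):
                if _can_pair(rna[k], rna[j]):
                    left = best[i][k - 1] if k > i else 0
                    if best[i][j] == left + 1 + best[k + 1][j - 1]:
                        structure[k], structure[j] = "(", ")"
                        if k > i:
                            traceback(i, k - 1)
                        i, j = k + 1, j - 1
                        break
            else:  # pragma: no cover - defensive; matrix guarantees a branch
                break

    traceback(0, n - 1)
    return "".join(structure)


def rnafold_available() -> bool:
    return shutil.which("RNAfold") is not None


def rnafold_fold(seq: str) -> str:
    """Dot-bracket of the MFE structure from an external RNAfold binary."""
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input=seq + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    # second output line: "structure ( mfe )"
    return proc.stdout.splitlines()[1].split()[0]


ENGINES = {"nussinov": nussinov_fold, "rnafold": rnafold_fold}


def get_engine(name: str = "nussinov"):
    try:
        return ENGINES[name]
    except KeyError:
        raise ValueError(f"unknown folding engine {name!r}; choose from {sorted(ENGINES)}")
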