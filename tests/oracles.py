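"""Independent brute-force oracles for the MM/ML codec tests.

Deliberately structured differently from the package implementation:
string splitting instead of a regex scan, and an explicit interleaving
walk for ML bytes.  Calls are reported as ``(position, base, strand,
code, ml_byte)`` tuples so comparisons are byte-exact.
"""

from __future__ import annotations


def oracle_decode(seq: str, mm: str, ml: list[int]):
    """Enumerate base occurrences and apply each delta as 'skip that
    many occurrences, then call the next'; one ML byte per (position,
    code) in tag order."""
    calls = []
    k = 0
    for item in mm.split(";"):
        if not item:
            continue
        base, strand, rest = item[0], item[1], item[2:]
        fields = rest.split(",")
        head = fields[0]
        if head and head[-1] in ".?":
            head = head[:-1]
        codes = [head] if head.isdigit() else list(head)
        deltas = [int(x) for x in fields[1:]]
        occurrences = [
            i for i, b in enumerate(seq) if base == "N" or b == base
        ]
        at = -1
        for delta in deltas:
            at += delta + 1
            for code in codes:
                calls.append((occurrences[at], base, strand, code, ml[k]))
                k += 1
    assert k == len(ml)
    return calls


def oracle_strip(seq: str, mm: str, ml: list[int], remove: set[str]):
    """Drop-policy strip: remove the interleaved bytes of the removed
    codes and keep everything else untouched."""
    kept = [c for c in oracle_decode(seq, mm, ml) if c[3] not in remove]
    return kept


def random_mod_tags(rng, seq: str, max_runs: int = 2, multi_code_prob: float = 0.4):
    """Construct a random valid (MM, ML) pair for ``seq``.

    Runs draw a base with at least one occurrence where possible, a
    skip flag, one or two codes, and a random subset of occurrence
    indices converted to deltas.
    """
    n_runs = int(rng.integers(0, max_runs + 1))
    items, ml = [], []
    used_keys = set()
    for _ in range(n_runs):
        base = str(rng.choice(list("ACGTN")))
        strand = str(rng.choice(["+", "-"]))
        if rng.random() < multi_code_prob:
            codes = "hm"
        else:
            codes = str(rng.choice(["m", "h", "a", "76792"]))
        code_keys = {(base, strand, c) for c in ([codes] if codes.isdigit() else codes)}
        if code_keys & used_keys:  # keep (position, code) pairs unique
            continue
        used_keys |= code_keys
        flag = str(rng.choice(["", ".", "?"]))
        occurrences = [i for i, b in enumerate(seq) if base == "N" or b == base]
        n_calls = int(rng.integers(0, len(occurrences) + 1)) if occurrences else 0
        chosen = sorted(rng.choice(len(occurrences), size=n_calls, replace=False)) if n_calls else []
        deltas, prev = [], -1
        for idx in chosen:
            deltas.append(int(idx) - prev - 1)
            prev = int(idx)
        code_list = [codes] if codes.isdigit() else list(codes)
        for _ in range(len(deltas) * len(code_list)):
            ml.append(int(rng.integers(0, 256)))
        items.append(base + strand + codes + flag + "".join(f",{d}" for d in deltas) + ";")
    return "".join(items), ml
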