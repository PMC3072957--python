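"""Correction-quality metrics against simulation ground truth.

Three views of a correction run:

* **Read classification** — detecting erroneous reads is a binary
  classification test: an erroneous read detected as erroneous is a true
  positive, an error-free read detected as erroneous a false positive, and
  so on.  Sensitivity = 100*TP/(TP+FN); specificity = 100*TN/(TN+FP).

* **Error rate** — total mismatching bases over total bases from a
  base-by-base comparison of each corrected read with its error-free
  original.  When lengths differ (a trimmed read), the shorter sequence is
  slid gaplessly along the longer one, the offset with the fewest
  mismatches is kept, and the shorter length enters the denominator.

* **Base accounting** — every originally erroneous base ends up in exactly
  one of: correct correction (CC, restored to the true base), incorrect
  correction (IC, changed to a third base), or error unchanged (EU);
  originally correct bases that were changed are errors introduced (EI).
  The rates are reported relative to the total number of original base
  errors: R_CC = 100*CC/(CC+IC+EU), R_IC = 100*IC/(CC+IC+EU) and
  R_EI = 100*EI/(CC+IC+EU).  Accounting needs a positional correspondence,
  so only equal-length pairs participate; runs meant for accounting should
  disable trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BaseAccounting",
    "ClassificationCounts",
    "ErrorRate",
    "account_bases",
    "classify",
    "error_rate",
]


@dataclass(frozen=True)
class ClassificationCounts:
    """Read-level confusion counts for erroneous-read detection."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        """100*TP/(TP+FN); None when no read is truly erroneous."""
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        """100*TN/(TN+FP); None when no read is truly error-free."""
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None


def classify(
    detected: Mapping[str, bool], truth: Mapping[str, bool]
) -> ClassificationCounts:
    """Confusion counts from per-read detected/true erroneous labels.

    ``detected[read_id]`` is True when the pipeline called the read
    erroneous; ``truth[read_id]`` when the simulator injected at least one
    error into it.  The two label sets must cover the same reads.
    """
    if set(detected) != set(truth):
        raise ValueError("detected and truth cover different read sets")
    tp = fp = fn = tn = 0
    for rid, det in detected.items():
        if truth[rid]:
            tp, fn = (tp + 1, fn) if det else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if det else (fp, tn + 1)
    return ClassificationCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class ErrorRate:
    """Mismatch total, base total, and their ratio."""

    mismatches: int
    bases: int

    @property
    def rate(self) -> float:
        return self.mismatches / self.bases if self.bases else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def _best_gapless_mapping(short: str, long: str) -> int:
    """Fewest mismatches of the shorter string slid gaplessly along the longer."""
    best = len(short) + 1
    for off in range(len(long) - len(short) + 1):
        mm = sum(a != b for a, b in zip(short, long[off : off + len(short)]))
        if mm < best:
            best = mm
    return best


def error_rate(pairs: Iterable[tuple[str, str]]) -> ErrorRate:
    """Per-base error rate over (corrected, original) sequence pairs.

    Equal-length pairs contribute a position-wise Hamming comparison over
    their full length; unequal pairs contribute the minimum-mismatch
    gapless offset and the shorter length.
    """
    mism = 0
    bases = 0
    for corrected, original in pairs:
        if len(corrected) == len(original):
            mism += sum(a != b for a, b in zip(corrected, original))
            bases += len(original)
        else:
            short, long = sorted((corrected, original), key=len)
            mism += _best_gapless_mapping(short, long)
            bases += len(short)
    return ErrorRate(mismatches=mism, bases=bases)


@dataclass(frozen=True)
class BaseAccounting:
    """Base-level fate counts of a correction run."""

    cc: int  # erroneous base restored to the true base
    ic: int  # erroneous base changed to a different wrong base
    eu: int  # erroneous base left unchanged
    ei: int  # correct base newly corrupted
    skipped_pairs: int = 0  # length-mismatched pairs excluded

    @property
    def total_errors(self) -> int:
        return self.cc + self.ic + self.eu

    @property
    def r_cc(self) -> float:
        return 100.0 * self.cc / self.total_errors if self.total_errors else 0.0

    @property
    def r_ic(self) -> float:
        return 100.0 * self.ic / self.total_errors if self.total_errors else 0.0

    @property
    def r_ei(self) -> float:
        return 100.0 * self.ei / self.total_errors if self.total_errors else 0.0


def account_bases(
    corrected: Mapping[str, str],
    originals: Mapping[str, str],
    errors: pd.DataFrame,
) -> BaseAccounting:
    """Classify every original error base as CC/IC/EU and count introduced errors.

    ``errors`` is the simulator's truth table with columns read_id, pos,
    true_base (the genome base) and read_base (the sequenced, wrong base).
    Reads present in ``corrected`` are evaluated; pairs whose corrected
    length differs from the original are skipped and counted.
    """
    err_by_read: dict[str, list[tuple[int, str, str]]] = {}
    for row in errors.itertuples(index=False):
        err_by_read.setdefault(row.read_id, []).append(
            (int(row.pos), row.true_base, row.read_base)
        )
    cc = ic = eu = ei = skipped = 0
    for rid, cor in corrected.items():
        orig = originals[rid]
        if len(cor) != len(orig):
            skipped += 1
            continue
        entries = err_by_read.get(rid, ())
        err_pos = set()
        for pos, true_b, read_b in entries:
            err_pos.add(pos)
            got = cor[pos]
            if got == true_b:
                cc += 1
            elif got == read_b:
                eu += 1
            else:
                ic += 1
        for j, (a, b) in enumerate(zip(cor, orig)):
            if a != b and j not in err_pos:
                ei += 1
    return BaseAccounting(cc=cc, ic=ic, eu=eu, ei=ei, skipped_pairs=skipped)
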