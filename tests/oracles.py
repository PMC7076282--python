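"""Independent reference implementations used to cross-check the package.

Everything here is written with explicit Python loops, no shared code with
``neurocal``, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import statistics


def brute_force_events(dff: list[float], d: list[float], threshold: float,
                       min_separation: int = 2, min_event_frames: int = 1,
                       baseline_window: int = 5) -> list[dict]:
    """Enumerate supra-threshold derivative runs by brute force.

    Returns a list of dicts with onset_frame, peak_frame, amplitude, duration
    following the same published rules as the detector: merge runs separated
    by fewer than ``min_separation`` sub-threshold frames, onset is the frame
    the first rise lands on, the peak search extends through the post-run
    decay to the first local minimum, and the amplitude baseline is the
    median dff over the window before onset.
    """
    n = len(dff)
    above = [i for i in range(len(d)) if d[i] > threshold]
    groups: list[list[int]] = []
    for i in above:
        if groups and (i - groups[-1][-1] - 1) < min_separation:
            groups[-1].append(i)
        else:
            groups.append([i])
    events = []
    for g in groups:
        if len(g) < min_event_frames:
            continue
        start, end = g[0], g[-1]
        onset = start + 1
        m = end + 1
        if m > n - 1:
            m = n - 1
        while m + 1 < n and dff[m + 1] < dff[m]:
            m += 1
        peak, best = onset, dff[onset]
        for t in range(onset, m + 1):
            if dff[t] > best:
                peak, best = t, dff[t]
        lo = onset - baseline_window
        if lo < 0:
            lo = 0
        base = statistics.median(dff[lo:onset]) if onset > lo else 0.0
        events.append({"onset_frame": onset, "peak_frame": peak,
                       "amplitude": dff[peak] - base,
                       "duration": end - start + 1})
    return events


def greedy_match(detected_onsets: list[int], true_frames: list[int],
                 tol: int = 2) -> int:
    """Number of detected onsets matchable to distinct true spikes within tol."""
    used: set[int] = set()
    matched = 0
    for o in detected_onsets:
        best, best_dist = None, tol + 1
        for j, t in enumerate(true_frames):
            if j in used:
                continue
            dist = abs(o - t)
            if dist <= tol and dist < best_dist:
                best, best_dist = j, dist
        if best is not None:
            used.add(best)
            matched += 1
    return matched


def f1_score(detected_by_cell: dict[str, list[int]],
             truth_by_cell: dict[str, list[int]], tol: int = 2) -> float:
    """Pooled F1 of onset detection with +-tol frame matching."""
    tp = fp = fn = 0
    for cid in truth_by_cell:
        det = sorted(detected_by_cell.get(cid, []))
        tru = list(truth_by_cell[cid])
        m = greedy_match(det, tru, tol)
        tp += m
        fp += len(det) - m
        fn += len(tru) - m
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
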