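"""Independent brute-force enactment of the suppression-profile rules,
written directly from the verbal procedure and kept free of the package's
vectorized implementation.  Used as the oracle in classification tests."""


def reference_classify(global_d, selective_d, threshold=0.2):
    global_d = list(map(float, global_d))
    selective_d = list(map(float, selective_d))

    def shown(d):
        return any(x > threshold for x in d)

    g_shown, s_shown = shown(global_d), shown(selective_d)
    if not g_shown and not s_shown:
        return "neither"
    if g_shown and not s_shown:
        return "global-only"
    if s_shown and not g_shown:
        return "selective-only"

    def peak(d):
        # increase at t relative to previous timepoints (running max, floored
        # at zero; first timepoint vs 0); increases <= threshold disqualify;
        # greatest increase wins, earliest timepoint on ties; if nothing
        # qualifies fall back to the plain greatest increase
        increases = []
        for t in range(len(d)):
            prior = max([0.0] + d[:t])
            increases.append(d[t] - prior)
        qualifying = [t for t, inc in enumerate(increases) if inc > threshold]
        pool = qualifying if qualifying else list(range(len(d)))
        best = pool[0]
        for t in pool[1:]:
            if increases[t] > increases[best]:
                best = t
        return best

    tg, ts = peak(global_d), peak(selective_d)
    if tg < ts:
        return "global-then-selective"
    if tg > ts:
        return "selective-then-global"
    return "same-time"
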