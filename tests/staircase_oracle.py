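"""Independent hand-coded trace of the two-phase staircase rules, used as an
oracle against the engine implementation."""


def trace_levels(correct_seq, start, f1, f2, n_down=3):
    levels = []
    level = start
    in_phase2 = False
    streak = 0
    for c in correct_seq:
        levels.append(level)
        if not in_phase2:
            if c:
                level = level / f1
            else:
                in_phase2 = True
                level = level * f2
                streak = 0
        else:
            if not c:
                level = level * f2
                streak = 0
            else:
                streak += 1
                if streak == n_down:
                    level = level / f2
                    streak = 0
    return levels
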