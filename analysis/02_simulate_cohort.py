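"""Generate the synthetic study cohort.

Ten subjects, each performing all six behaviors (natural head movement,
left/right chewing, left/right wink, talking) for 20 consecutive 3-second
windows per class at 100 Hz, with subject-specific pre-loads, gains, chewing
rates and side dominance, and food texture cycling bread/chip/jelly across
subjects.

Writes one CSV per subject plus a manifest under results/cohort/.
"""

from pathlib import Path

from hingeforce.synthetic import generate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
N_SUBJECTS = 10
WINDOWS_PER_CLASS = 20
SEED = 1


def main() -> None:
    cohort = generate_cohort(N_SUBJECTS, WINDOWS_PER_CLASS, seed=SEED)
    manifest = write_cohort(cohort, OUT)
    total_s = sum(rec.duration_s for rec in cohort)
    print(f"{len(cohort)} subjects, {total_s / 60:.0f} min of signal total")
    for rec in cohort[:3]:
        p = rec.subject
        print(f"  {p.subject_id}: chew {p.chew_freq:.2f} Hz, "
              f"dominance x{p.dominant_side_ratio:.1f}, "
              f"preload {p.preload_left:.1f}/{p.preload_right:.1f} N")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
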