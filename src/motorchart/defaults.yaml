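# Default parameterization of the synthetic infant-motor cohort generator.
#
# All ages/developmental stages `d` are in months.  Posture probabilities at
# stage d are softmax(z_p(d)) with per-posture quadratic logits
#   z_p(d) = a + b*d + c*d^2
# chosen so that the monthly mean curves show the canonical gross-motor
# sequence: supine lying declines first, prone lying declines next, crawl
# posture shows a transient mid-range peak (~10 months), and sitting then
# standing rise and persist.
#
# Movement maturation within a posture is a cumulative-logit ordinal model
# over still < proto < elementary < fluent:
#   P(level >= j | d) = sigmoid(rate * (d - threshold_j - posture_offset))
# with thresholds increasing in d, plus small fixed probabilities for the
# non-ordinal movements (pivot / roll / transition) in the postures where
# they occur; the ordinal block is rescaled to fill the remaining mass.

categories:
  postures: [supine, prone, side, crawl, sitting, standing]
  movements: [still, proto, elementary, fluent, pivot, roll, transition]

posture_trajectories:        # logit coefficients [a, b, c]
  supine:   [ 3.0, -0.55,  0.0]
  prone:    [ 1.8, -0.28,  0.0]
  side:     [-1.0, -0.10,  0.0]
  crawl:    [-5.5,  1.00, -0.05]   # transient peak at d = 10 months
  sitting:  [-2.6,  0.33,  0.0]
  standing: [-8.0,  0.65,  0.0]

movement_maturation:
  rate: 0.7                  # 1/months; steepness of ordinal transitions
  thresholds: [5.0, 9.0, 13.0]   # months at which proto/elementary/fluent emerge
  posture_offsets:           # months; movements mature earliest in supine
    supine: -2.0
    prone: -1.0
    side: -1.0
    crawl: 1.0
    sitting: 0.0
    standing: 2.0
  extras:                    # fixed probabilities of non-ordinal movements
    supine:   {roll: 0.06, transition: 0.03}
    prone:    {pivot: 0.08, roll: 0.04, transition: 0.03}
    side:     {roll: 0.08, transition: 0.04}
    crawl:    {transition: 0.05}
    sitting:  {transition: 0.04}
    standing: {transition: 0.04}

# Distribution used for frames outside free play (carried, resting, feeding):
# posture mix independent of age, movement overwhelmingly still.  This is
# what makes 10-minute windows of non-playtime separable from playtime.
nonplay_distribution:
  posture: {supine: 0.35, prone: 0.05, side: 0.10, crawl: 0.02, sitting: 0.40, standing: 0.08}
  movement: {still: 0.75, proto: 0.10, elementary: 0.06, fluent: 0.04, pivot: 0.01, roll: 0.02, transition: 0.02}

# Physical growth median curves mu_k(t), strictly monotone on [4, 18] months:
#   linear_log:  mu(t) = a + b * log(1 + t / t0)
#   power:       mu(t) = a + b * t ** c
# sigma_subj is the SD of the per-subject random intercept, sigma_meas the
# per-visit measurement error SD (units of the modality).  The noise-to-slope
# ratio makes length the tightest age predictor and weight/HC the loosest,
# matching how these modalities behave in growth-chart practice.
physical_curves:
  length_cm: {form: linear_log, a: 46.0, b: 16.0, t0: 2.0, sigma_subj: 2.2, sigma_meas: 0.5}
  weight_kg: {form: power, a: 2.0, b: 2.2, c: 0.5, sigma_subj: 1.1, sigma_meas: 0.15}
  hc_cm:     {form: linear_log, a: 33.0, b: 4.6, t0: 1.0, sigma_subj: 1.2, sigma_meas: 0.25}

# Cohort sampling plan
cohort:
  n_subjects: 60
  age_range_months: [4.0, 18.0]
  recordings_per_subject: [1, 7]     # uniform integer range
  # sessions run from morning dressing to evening sleep: 1.4-16.9 h,
  # averaging ~7.8 h, of which roughly 30% is free play and ~20% is lost
  # to signal dropouts
  session_hours: {mean: 7.8, sd: 3.5, min: 1.4, max: 16.9}   # truncated normal
  playtime_fraction: 0.30
  carried_fraction: 0.10
  lowquality_fraction: 0.20
  mean_block_minutes: 5.0            # mean length of carried / low-quality blocks
  mean_play_block_minutes: 30.0      # mean length of playtime / non-playtime periods
  sigma_dev: 0.6                     # months; per-subject developmental offset SD
  sigma_sess: 0.85                   # months; per-session situational offset SD
  p_stay: 0.9                        # frame-to-frame label persistence
  visits_per_subject: [2, 5]         # physical growth visit count (uniform range)
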