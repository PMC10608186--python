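# Default archetype registry: 10 non-NH and 6 NH nocturnal glucose patterns.
#
# Each archetype is a piecewise-linear mean trajectory (time in decimal hours
# after midnight, level in mmol/L) plus AR(1) noise.  Initial/final levels sit
# at the published cluster medians (trajectories are flat across the first and
# last three 5-min slots so the slot-0..2 / slot-69..71 means hit the anchors
# exactly), and NH archetypes dip below 3.9 mmol/L for >=15 min inside their
# published episode window.  Interior breakpoint levels were chosen
# numerically so that, after per-series standardization (which removes level
# and scale), the 10 non-NH shape directions have pairwise cosine <= 0.38 and
# the 6 NH ones <= 0.31: per-series standardization keeps only trajectory
# shape, so distinct patterns must be distinct directions, not just distinct
# levels.  The resulting curves keep each pattern's qualitative character
# (stable / uptrend / downtrend and its timing) but carry larger intra-night
# excursions than the word "stable" suggests for real nights.
archetypes:
  # ---- non-NH patterns ----
  - name: non_nh_01   # near-normal and flat at both ends, mid-night hump
    group: NON_NH
    breakpoints: [[0.0, 6.1], [0.3, 6.1], [1.0, 5.6], [1.8, 5.5], [2.6, 6.3],
                  [3.4, 8.0], [4.2, 9.4], [5.0, 8.7], [5.7, 6.0], [6.0, 6.0]]
  - name: non_nh_02   # stable at a higher level; early peak, late trough
    group: NON_NH
    breakpoints: [[0.0, 7.7], [0.3, 7.7], [1.0, 8.1], [1.8, 9.4], [2.6, 10.5],
                  [3.4, 9.2], [4.2, 6.5], [5.0, 5.9], [5.7, 7.8], [6.0, 7.8]]
  - name: non_nh_03   # slightly elevated start, net decline with a mid-night wobble
    group: NON_NH
    breakpoints: [[0.0, 9.1], [0.3, 9.1], [1.0, 7.2], [1.8, 7.1], [2.6, 9.2],
                  [3.4, 10.4], [4.2, 9.1], [5.0, 7.0], [5.7, 5.6], [6.0, 5.6]]
  - name: non_nh_04   # marked hyperglycemia, steep early decline then drift down
    group: NON_NH
    breakpoints: [[0.0, 15.8], [0.3, 15.8], [1.0, 13.9], [1.8, 12.7], [2.6, 12.4],
                  [3.4, 12.4], [4.2, 12.1], [5.0, 11.5], [5.7, 10.7], [6.0, 10.7]]
  - name: non_nh_05   # stable hyperglycemia; early rise, mid-night dip, recovery
    group: NON_NH
    breakpoints: [[0.0, 13.4], [0.3, 13.4], [1.0, 16.1], [1.8, 16.2], [2.6, 13.9],
                  [3.4, 12.1], [4.2, 12.4], [5.0, 13.2], [5.7, 13.5], [6.0, 13.5]]
  - name: non_nh_06   # hyperglycemia, early rise then late decline
    group: NON_NH
    breakpoints: [[0.0, 11.7], [0.3, 11.7], [1.0, 14.7], [1.8, 15.3], [2.6, 14.2],
                  [3.4, 14.0], [4.2, 14.7], [5.0, 13.6], [5.7, 10.4], [6.0, 10.4]]
  - name: non_nh_07   # hyperglycemia with an early uptrend, high plateau
    group: NON_NH
    breakpoints: [[0.0, 10.2], [0.3, 10.2], [1.0, 12.0], [1.8, 13.9], [2.6, 14.9],
                  [3.4, 14.5], [4.2, 13.7], [5.0, 13.7], [5.7, 14.0], [6.0, 14.0]]
  - name: non_nh_08   # near-normal start, pronounced late uptrend
    group: NON_NH
    breakpoints: [[0.0, 7.4], [0.3, 7.4], [1.0, 7.7], [1.8, 7.9], [2.6, 7.9],
                  [3.4, 8.1], [4.2, 8.9], [5.0, 10.5], [5.7, 12.4], [6.0, 12.4]]
  - name: non_nh_09   # moderate hyperglycemia, early decline with rebound
    group: NON_NH
    breakpoints: [[0.0, 10.3], [0.3, 10.3], [1.0, 7.4], [1.8, 5.6], [2.6, 5.8],
                  [3.4, 7.3], [4.2, 8.6], [5.0, 8.7], [5.7, 8.0], [6.0, 8.0]]
  - name: non_nh_10   # slightly elevated, long shallow dip then late rise
    group: NON_NH
    breakpoints: [[0.0, 9.2], [0.3, 9.2], [1.0, 8.1], [1.8, 7.3], [2.6, 6.6],
                  [3.4, 5.7], [4.2, 5.5], [5.0, 7.2], [5.7, 10.1], [6.0, 10.1]]

  # ---- NH patterns ----
  - name: nh_01       # low at midnight (episode from slot 0), strong uptrend
    group: NH
    nh_window: [0.0, 1.1]
    breakpoints: [[0.0, 3.4], [0.2, 3.4], [0.75, 3.2], [1.1, 4.5], [2.0, 6.6], [3.0, 4.5],
                  [4.0, 4.5], [5.0, 9.1], [5.7, 14.1], [6.0, 14.1]]
  - name: nh_02       # near-normal start, early episode, marked post-event rise
    group: NH
    nh_window: [0.3, 2.0]
    breakpoints: [[0.0, 5.2], [0.25, 5.2], [0.8, 3.2], [1.5, 3.2], [2.2, 4.8],
                  [3.0, 9.8], [3.8, 14.0], [4.6, 12.8], [5.5, 9.8], [6.0, 9.8]]
  - name: nh_03       # near-normal start, episode in the first two hours, overshoot recovery
    group: NH
    nh_window: [0.7, 2.2]
    breakpoints: [[0.0, 5.1], [0.5, 5.1], [1.0, 3.2], [1.8, 3.2], [2.6, 7.9],
                  [3.4, 5.5], [4.2, 4.4], [5.0, 4.4], [5.7, 6.3], [6.0, 6.3]]
  - name: nh_04       # gentle downtrend, mid-night episode, weak recovery
    group: NH
    nh_window: [1.6, 3.8]
    breakpoints: [[0.0, 5.2], [0.5, 5.2], [1.2, 5.4], [2.1, 3.2], [3.4, 3.2],
                  [4.2, 6.8], [5.0, 6.6], [5.7, 4.3], [6.0, 4.3]]
  - name: nh_05       # initial hyperglycemia, decline after 2 a.m., episode at 4-6 a.m.
    group: NH
    nh_window: [4.0, 6.0]
    breakpoints: [[0.0, 10.0], [0.2, 10.0], [0.7, 9.4], [1.4, 9.6], [2.1, 9.7], [3.3, 8.2],
                  [4.6, 3.4], [5.7, 3.4], [6.0, 3.4]]
  - name: nh_06       # initial hyperglycemia, downtrend from midnight, episode at 2-4 a.m.
    group: NH
    nh_window: [2.3, 4.0]
    breakpoints: [[0.0, 9.4], [0.5, 9.4], [1.5, 6.8], [2.9, 3.2], [3.6, 3.2],
                  [4.4, 4.5], [5.0, 5.6], [5.7, 6.4], [6.0, 6.4]]
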