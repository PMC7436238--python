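"""The two bespoke evaluation metrics, on hand-made prediction tracks.

Correspondence-mapped accuracy forgives transition-zone confusions (e.g.
predicted Barrett against a true Z-line transition counts as correct);
switch counting measures temporal stability — an ideal pullback prediction
switches exactly 4 times, once per anatomical boundary.
"""

from pullbacknet import (
    CorrespondenceMap,
    count_label_switches,
    is_true_positive,
    label_accuracy,
    mean_label_accuracy,
)

# the correspondence map in action
print("predicted B  vs true Tz ->", is_true_positive("B", "Tz"))   # accepted
print("predicted St vs true Sq ->", is_true_positive("St", "Sq"))  # rejected

# mapped vs plain accuracy on one track
pred = ["B"] * 4
truth = ["Tz", "B", "Ts", "Sq"]
print("mapped accuracy :", label_accuracy(pred, truth))                        # 0.75
print("plain  accuracy :", label_accuracy(pred, truth,
                                          cmap=CorrespondenceMap.identity()))  # 0.25

# stability: an ideal single-run-per-class track vs a flickering one
ideal = ["St"] * 13 + ["Tz"] * 15 + ["B"] * 47 + ["Ts"] * 21 + ["Sq"] * 4
flicker = ideal.copy()
flicker[40:60:4] = ["Sq"] * 5  # five isolated wrong frames inside the B run
print("ideal track switches   :", count_label_switches(ideal))     # 4
print("flicker track switches :", count_label_switches(flicker))   # 4 + 2*5 = 14

# the headline score averages per PATIENT, so a short video counts as much
# as a long one
print("mean label accuracy of patients (1.0, 0.5):",
      mean_label_accuracy([1.0, 0.5]))  # 0.75 regardless of video lengths
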