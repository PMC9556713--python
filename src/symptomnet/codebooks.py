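"""Standard symptom codebook: the 38 cancer symptoms assessed weekly during
chemotherapy, with their conventional short codes."""

from .io import SymptomCodebook

CANCER_SYMPTOMS_38 = SymptomCodebook({
    "Energy": "Lack of Energy",
    "Difsleep": "Difficulty Sleeping",
    "Pain": "Pain",
    "Drowsy": "Feeling Drowsy",
    "Hairloss": "Hair Loss",
    "Numb": "Numbness or Tingling in Hands or Feet",
    "Worry": "Worrying",
    "Difcon": "Difficulty Concentrating",
    "Taste": "Change in the Way Food Tastes",
    "Nausea": "Nausea",
    "Sad": "Feeling Sad",
    "Drymouth": "Dry Mouth",
    "Constipat": "Constipation",
    "Irritable": "Feeling Irritable",
    "Appetite": "Lack of Appetite",
    "Myself": "I Do Not Look Like Myself",
    "Skin": "Changes in Skin",
    "Nervous": "Feeling Nervous",
    "Bloat": "Feeling Bloated",
    "Hotflash": "Hot Flashes",
    "Sweats": "Sweats",
    "Cough": "Cough",
    "Dizzy": "Dizziness",
    "Diarrhea": "Diarrhea",
    "Sexual": "Problems with Sexual Interest or Activity",
    "Increaseapp": "Increased Appetite",
    "Sob": "Shortness of Breath",
    "Wtgain": "Weight Gain",
    "Itch": "Itching",
    "Wtloss": "Weight Loss",
    "Abdominal": "Abdominal Cramps",
    "Mouthsore": "Mouth Sore",
    "Difbreath": "Difficulty Breathing",
    "Chest": "Chest Tightness",
    "Swelling": "Swelling",
    "Urinate": "Problems with Urination",
    "Swallow": "Difficulty Swallowing",
    "Vomit": "Vomitting",
})
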