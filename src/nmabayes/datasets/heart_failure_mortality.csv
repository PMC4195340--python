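study,treatment,events,n
CARE_HF-ext,Medical therapy,154,404
CARE_HF-ext,Cardiac resynchronization,101,409
COMPANION,Medical therapy,77,308
COMPANION,Cardiac resynchronization,131,617
COMPANION,Combined resynchronization and defibrillator,105,595
MIRACLE,Medical therapy,16,225
MIRACLE,Cardiac resynchronization,12,228
MUSTIC-SR,Medical therapy,0,29
MUSTIC-SR,Cardiac resynchronization,1,29
SCD-HeFT,Medical therapy,244,847
SCD-HeFT,Implantable defibrillator,182,829
SCD-HeFT,Amiodarone,240,845
MADIT-II,Medical therapy,97,490
MADIT-II,Implantable defibrillator,105,742
DEFINITE,Medical therapy,40,229
DEFINITE,Implantable defibrillator,28,229
CAT,Medical therapy,17,54
CAT,Implantable defibrillator,13,50
MIRACLE-ICD-I,Implantable defibrillator,5,182
MIRACLE-ICD-I,Combined resynchronization and defibrillator,4,187
MIRACLE-ICD-II,Implantable defibrillator,2,101
MIRACLE-ICD-II,Combined resynchronization and defibrillator,2,85
CONTAK-CD,Implantable defibrillator,16,245
CONTAK-CD,Combined resynchronization and defibrillator,11,245
AMIOVIRT,Implantable defibrillator,6,51
AMIOVIRT,Amiodarone,7,52
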