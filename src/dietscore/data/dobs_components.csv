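component,polarity,rule,transform
fiber,anti_oxidant,tertile,identity
beta_carotene,anti_oxidant,tertile,log
riboflavin,anti_oxidant,tertile,identity
niacin,anti_oxidant,tertile,identity
vitamin_b6,anti_oxidant,tertile,identity
folate,anti_oxidant,tertile,identity
vitamin_b12,anti_oxidant,tertile,log
vitamin_c,anti_oxidant,tertile,log
vitamin_e,anti_oxidant,tertile,identity
calcium,anti_oxidant,tertile,identity
magnesium,anti_oxidant,tertile,identity
zinc,anti_oxidant,tertile,identity
copper,anti_oxidant,tertile,identity
selenium,anti_oxidant,tertile,identity
total_fat,pro_oxidant,tertile,identity
iron,pro_oxidant,tertile,identity
alcohol,pro_oxidant,alcohol_category,identity
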