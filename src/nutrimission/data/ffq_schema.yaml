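# Default FFQ schemas: the 20-item full instrument (3-month recall) and the
# 13-item short monthly variant (one representative item per food group).
#
# EDITORIAL NOTE: the published questionnaire's exact item wording is not
# reproduced here; item count (20), the food-group mapping, and coverage of
# every mission food group are the normative parts.  Portion text uses
# household measures.

schemas:
  full:
    schema_id: ffq_full_v1
    version: full
    items:
      - item_id: fresh_fruit
        food_group_id: fruits
        label: Fresh fruit
        representative_foods: [apple, orange, banana, pear, seasonal fruit]
        portion_description: 1 medium piece or 1 cup chopped
      - item_id: raw_vegetables
        food_group_id: vegetables
        label: Raw vegetables and salads
        representative_foods: [lettuce, tomato, carrot, cucumber]
        portion_description: 1 bowl of salad or 1 cup raw
      - item_id: cooked_vegetables
        food_group_id: vegetables
        label: Cooked vegetables
        representative_foods: [chard, green beans, broccoli, courgette]
        portion_description: 1 plate as main or side
      - item_id: pulses
        food_group_id: pulses
        label: Pulses
        representative_foods: [lentils, chickpeas, beans, peas]
        portion_description: 1 plate cooked (about 60-80 g dry)
      - item_id: nuts
        food_group_id: nuts
        label: Unsalted natural nuts
        representative_foods: [walnuts, almonds, hazelnuts, pistachios, cashews]
        portion_description: 1 handful (about 20-30 g)
      - item_id: wholegrain_bread
        food_group_id: wholegrains
        label: Wholegrain bread
        representative_foods: [wholemeal bread, rye bread]
        portion_description: 2 slices or 1 roll
      - item_id: wholegrain_cereals
        food_group_id: wholegrains
        label: Wholegrain pasta, rice and cereals
        representative_foods: [brown rice, wholewheat pasta, oats]
        portion_description: 1 plate cooked
      - item_id: olive_oil
        food_group_id: olive_oil
        label: Virgin olive oil
        representative_foods: [virgin olive oil for cooking and dressing]
        portion_description: 1 tablespoon
      - item_id: water
        food_group_id: water
        label: Water as main drink
        representative_foods: [tap water, mineral water, infusions without sugar]
        portion_description: 1 glass (200-250 mL)
      - item_id: white_fish
        food_group_id: fish
        label: White fish
        representative_foods: [hake, cod, monkfish, sole]
        portion_description: 1 fillet (125-150 g)
      - item_id: oily_fish
        food_group_id: fish
        label: Oily fish and seafood
        representative_foods: [sardines, salmon, mackerel, mussels]
        portion_description: 1 serving (125-150 g)
      - item_id: milk_yogurt
        food_group_id: dairy
        label: Milk and plain yogurt
        representative_foods: [milk, plain yogurt, kefir]
        portion_description: 1 glass of milk or 1-2 yogurts
      - item_id: cheese
        food_group_id: dairy
        label: Cheese
        representative_foods: [fresh cheese, cured cheese]
        portion_description: 2-3 slices (40-60 g)
      - item_id: red_meat
        food_group_id: red_meat
        label: Red meat
        representative_foods: [beef, pork, lamb]
        portion_description: 1 serving (100-125 g)
      - item_id: cold_meats
        food_group_id: processed_meat
        label: Cold meats and cured charcuterie
        representative_foods: [ham, salami, chorizo, mortadella]
        portion_description: 3-4 slices (30-40 g)
      - item_id: processed_meat_products
        food_group_id: processed_meat
        label: Sausages and other processed meat products
        representative_foods: [sausages, burgers from processed meat, bacon]
        portion_description: 1 serving (100 g)
      - item_id: sugary_drinks
        food_group_id: sugary_foods
        label: Sugary drinks
        representative_foods: [soft drinks, sweetened juices, energy drinks]
        portion_description: 1 can or glass (250-330 mL)
      - item_id: sweets_pastries
        food_group_id: sugary_foods
        label: Sweets and pastries
        representative_foods: [biscuits, industrial pastries, chocolate bars]
        portion_description: 1 unit or small serving
      - item_id: salty_snacks
        food_group_id: ultraprocessed
        label: Ultra-processed salty snacks
        representative_foods: [crisps, snack bars, salted crackers]
        portion_description: 1 small bag or bowl
      - item_id: ready_meals
        food_group_id: ultraprocessed
        label: Ready meals and fast food
        representative_foods: [pizza, precooked dishes, fast-food menus]
        portion_description: 1 dish or menu

  short:
    schema_id: ffq_short_v1
    version: short
    items:
      - {item_id: fresh_fruit, food_group_id: fruits, label: Fresh fruit}
      - {item_id: raw_vegetables, food_group_id: vegetables, label: Raw vegetables and salads}
      - {item_id: pulses, food_group_id: pulses, label: Pulses}
      - {item_id: nuts, food_group_id: nuts, label: Unsalted natural nuts}
      - {item_id: wholegrain_bread, food_group_id: wholegrains, label: Wholegrain bread}
      - {item_id: olive_oil, food_group_id: olive_oil, label: Virgin olive oil}
      - {item_id: water, food_group_id: water, label: Water as main drink}
      - {item_id: white_fish, food_group_id: fish, label: White fish}
      - {item_id: milk_yogurt, food_group_id: dairy, label: Milk and plain yogurt}
      - {item_id: red_meat, food_group_id: red_meat, label: Red meat}
      - {item_id: cold_meats, food_group_id: processed_meat, label: Cold meats and cured charcuterie}
      - {item_id: sugary_drinks, food_group_id: sugary_foods, label: Sugary drinks}
      - {item_id: ready_meals, food_group_id: ultraprocessed, label: Ready meals and fast food}
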