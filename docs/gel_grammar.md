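# The Gel dialect — grammar

This package implements a documented dialect of a graph-exploration
language. The original system's concrete syntax is only partially public,
so this grammar is the dialect's own specification; everything the
interpreter accepts is defined here.

## Lexical rules

- Identifiers: `[A-Za-z_][A-Za-z0-9_]*`.
- Integers: decimal digit runs. Reals: `1.5`, `.5`, `2e-3`, `1.5e+2`.
- Strings: double-quoted, escapes `\" \\ \n \t \r \uXXXX`.
- Comments: `#` to end of line.
- Statements terminate with `;`.
- Dotted operators vs. reals: a dot followed by a digit starts a real
  literal only when the previous token could not end a value; otherwise the
  dotted-operator reading wins. So `A.+B` is `A .+ B`, `1.+2` is
  `1 .+ 2`, and `0.4` is a single real.

## EBNF

```
program       = { statement } ;
statement     = nodetype_decl | linktype_decl | graph_decl
              | assignment | command ;

nodetype_decl = "nodetype" IDENT "(" [ attr_list ] ")" ";" ;
linktype_decl = "linktype" IDENT ( "[" [ attr_list ] "]"      (* undirected *)
                                 | "<" [ attr_list ] ">" )    (* directed   *)
                ";" ;
attr_list     = attr { "," attr } ;
attr          = IDENT ":" ptype [ "=" literal ] ;
ptype         = "string" | "int" | "float" | "double" ;

graph_decl    = "graph" IDENT ":" IDENT "," IDENT
                [ "=" "{" { literal_item ";" } "}" ] ";" ;
literal_item  = node_literal | link_literal ;
node_literal  = name "(" [ kv_list ] ")" ;
link_literal  = name "-"  name "[" [ kv_list ] "]"            (* undirected *)
              | name "->" name "<" [ kv_list ] ">" ;          (* directed   *)
name          = IDENT | STRING ;
kv_list       = IDENT "=" literal { "," IDENT "=" literal } ;
literal       = [ "-" ] NUMBER | STRING ;

assignment    = IDENT assign_op graph_expr ";" ;
assign_op     = "=" | "+=" | ".+=" | "-=" | ".-="
              | "&=" | ".&=" | "*=" | "**=" ;
graph_expr    = graph_term { bin_op graph_term } ;            (* left fold  *)
graph_term    = IDENT | "(" graph_expr ")" ;
bin_op        = ".+" | "+" | ".-" | "-" | ".&" | "&" | "*" | "**" ;

command       = "import" IDENT STRING ";"
              | "export" IDENT STRING [ "visual" ] ";"
              | "save"   IDENT STRING ";"
              | "select" IDENT "=" IDENT ("nodes"|"links") "where" expr ";"
              | "foreach" IDENT ("nodes"|"links") [ "where" expr ]
                  ( "set" IDENT ":=" expr { "," IDENT ":=" expr }
                  | "tally" reducer { "," reducer } ) ";"
              | "list" ";"
              | "help" ";" ;
reducer       = "count" | ("sum"|"min"|"max") "(" expr ")" ;

expr          = or_expr ;
or_expr       = and_expr { "or" and_expr } ;
and_expr      = not_expr { "and" not_expr } ;
not_expr      = "not" not_expr | comparison ;
comparison    = arith [ ("<"|"<="|"=="|"!="|">="|">") arith ] ;
arith         = term { ("+"|"-") term } ;
term          = factor { ("*"|"/") factor } ;
factor        = "-" factor | "(" expr ")" | NUMBER | STRING
              | "true" | "false" | "degree" "(" ")" | IDENT ;
```

## Semantics, briefly

- All eight graph operators share **one precedence level** and associate to
  the left, so chains such as `G * G - G` evaluate exactly as written.
  A precedence hierarchy would silently change the meaning of published
  operator chains, so none is imposed; use parentheses to regroup.
- `G = expr` coerces the result into `G`'s declared type if `G` was
  declared with a `graph` statement (attribute promotion); compound forms
  (`G .+= H`) rebind `G` to the operator result, whose type is always the
  left operand's.
- Declarations must precede use; evaluation is strictly top-to-bottom; an
  error aborts at the failing statement and names its line.
- `import` infers the delimiter from the extension (`.tsv`/`.tab` = tab,
  otherwise comma).
- In `foreach ... set`, all right-hand sides see the record's pre-update
  values (snapshot semantics), so results never depend on iteration order.
- `degree()` is available in node expressions only; a self-loop counts 1.

Out of scope (deliberately): user-defined functions, loops/conditionals
beyond `foreach`, plug-ins, and command families the original system leaves
undefined (object modification, simulation, and so on).
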